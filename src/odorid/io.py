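"""Readers and writers for the canonical endpoint CSV schema.

Two dialects are supported:

* ``wide`` (canonical): one row per fused sample with the metadata columns
  ``participant, day, kind, region, replicate`` followed by the 20 feature
  columns ``d1_s1 .. d2_s10``.
* ``long``: one row per device x sensor with columns
  ``participant, day, kind, region, replicate, device, sensor, endpoint``;
  rows carrying the same sample key are fused into a wide row in canonical
  order (device 1 sensors first), independent of row order in the file.

Also provides endpoint extraction from raw 10-channel time series and the
fusion of per-device records into 20-feature vectors.
"""

from __future__ import annotations

import csv
from dataclasses import replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    META_COLUMNS,
    EndpointTable,
    MeasurementRecord,
    SchemaError,
    ValidationError,
    feature_columns,
)

LONG_COLUMNS = list(META_COLUMNS) + ["device", "sensor", "endpoint"]

_FLOAT_FMT = "%.17g"  # 17 significant digits: exact float64 round-trips


def write_endpoint_csv(table: EndpointTable, path: str | Path, dialect: str = "wide") -> None:
    """Write *table* to *path*; lossless, stable column order, UTF-8."""
    path = Path(path)
    if dialect == "wide":
        frame = table.frame[list(META_COLUMNS) + table.features]
        _write_frame(frame, path)
    elif dialect == "long":
        rows = []
        for _, row in table.frame.iterrows():
            for col in table.features:
                dev, sen = _parse_feature_name(col)
                rows.append(
                    {
                        **{c: row[c] for c in META_COLUMNS},
                        "device": dev,
                        "sensor": sen,
                        "endpoint": row[col],
                    }
                )
        _write_frame(pd.DataFrame(rows, columns=LONG_COLUMNS), path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_endpoint_csv(path: str | Path, dialect: str = "wide") -> EndpointTable:
    """Read a canonical CSV into a validated :class:`EndpointTable`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, keep_default_na=False, na_values=[], dtype=str)
    if dialect == "wide":
        return _table_from_wide(raw)
    if dialect == "long":
        return _table_from_long(raw)
    raise ValueError(f"unknown dialect {dialect!r}")


def extract_endpoints(record: MeasurementRecord, window: int = 1) -> MeasurementRecord:
    """Condense a record's time series to per-sensor endpoints.

    The endpoint of each channel is the final time sample (the value the
    sensor reaches at the end of the 50 s measurement phase).  ``window > 1``
    averages the last *window* samples instead, for robustness experiments.
    """
    if record.series is None or record.series.size == 0:
        raise ValidationError("record has no time series to condense")
    if window < 1:
        raise ValueError("endpoint window must be >= 1")
    series = np.asarray(record.series, dtype=float)
    if series.shape[1] < window:
        raise ValidationError("time series shorter than endpoint window")
    tail = series[:, -window:]
    if np.isnan(tail).any():
        raise ValidationError("NaN in final time sample(s)")
    endpoints = tail.mean(axis=1)
    return replace(record, endpoints=endpoints)


def fuse_records(records: Sequence[MeasurementRecord]) -> np.ndarray:
    """Fuse per-device records of one sample into the canonical vector.

    Pure reordering: device 1 sensors 1..10 then device 2 sensors 1..10.
    Every device from 1..max must appear exactly once with endpoints present.
    """
    by_device = {}
    for rec in records:
        if rec.endpoints is None:
            raise ValidationError(f"device {rec.device} record has no endpoints")
        if rec.device in by_device:
            raise ValidationError(f"duplicate record for device {rec.device}")
        by_device[rec.device] = rec.endpoints
    expected = set(range(1, max(by_device) + 1))
    if set(by_device) != expected:
        raise ValidationError(
            f"device-incomplete sample: have {sorted(by_device)}, expected {sorted(expected)}"
        )
    return np.concatenate([by_device[d] for d in sorted(by_device)])


# -- internals ------------------------------------------------------------


def _write_frame(frame: pd.DataFrame, path: Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(frame.columns)
        for row in frame.itertuples(index=False):
            out = []
            for value in row:
                if value is None or (isinstance(value, float) and np.isnan(value)) or value is pd.NA:
                    out.append("")
                elif isinstance(value, (float, np.floating)):
                    out.append(_FLOAT_FMT % value)
                else:
                    out.append(value)
            writer.writerow(out)


def _parse_feature_name(name: str) -> tuple[int, int]:
    try:
        dev, sen = name.split("_")
        return int(dev.lstrip("d")), int(sen.lstrip("s"))
    except Exception as exc:  # pragma: no cover - defensive
        raise SchemaError(f"feature column {name!r} is not of the form d<dev>_s<sen>") from exc


def _require_columns(frame: pd.DataFrame, needed: Sequence[str]) -> None:
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing column(s): {missing}")


def _table_from_wide(raw: pd.DataFrame) -> EndpointTable:
    _require_columns(raw, META_COLUMNS)
    features = [c for c in raw.columns if c not in META_COLUMNS]
    if not features:
        raise SchemaError("wide CSV has no feature columns (d<dev>_s<sen>)")
    # keep canonical ordering regardless of file column order
    features.sort(key=_parse_feature_name)
    frame = raw.copy()
    for col in features:
        # numpy's strtod is correctly rounded; pandas' fast parser is not
        frame[col] = np.asarray(frame[col].to_numpy(), dtype=np.float64)
    frame["region"] = frame["region"].replace("", None)
    frame["replicate"] = frame["replicate"].replace("", None)
    frame = frame[list(META_COLUMNS) + features]
    return EndpointTable(frame=frame, features=features)


def _table_from_long(raw: pd.DataFrame) -> EndpointTable:
    _require_columns(raw, LONG_COLUMNS)
    frame = raw.copy()
    frame["endpoint"] = np.asarray(frame["endpoint"].to_numpy(), dtype=np.float64)
    frame["device"] = frame["device"].astype(int)
    frame["sensor"] = frame["sensor"].astype(int)
    n_devices = int(frame["device"].max())
    sensors = int(frame["sensor"].max())
    features = feature_columns(n_devices, sensors)
    key_cols = list(META_COLUMNS)
    rows = []
    for key, group in frame.groupby(key_cols, sort=True, dropna=False):
        expected = n_devices * sensors
        pairs = list(zip(group["device"], group["sensor"]))
        if len(pairs) != expected or len(set(pairs)) != expected:
            raise ValidationError(
                f"device-incomplete or duplicated sample {dict(zip(key_cols, key))}: "
                f"{len(pairs)} device/sensor rows, expected {expected}"
            )
        ordered = group.sort_values(["device", "sensor"])
        rows.append(dict(zip(key_cols, key), **dict(zip(features, ordered["endpoint"]))))
    out = pd.DataFrame(rows, columns=key_cols + features)
    out["region"] = out["region"].replace("", None)
    out["replicate"] = out["replicate"].replace("", None)
    return EndpointTable(frame=out, features=features)
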