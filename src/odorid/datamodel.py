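"""Canonical data model for eNose endpoint data.

A *measurement* is one run of a single 10-sensor metal-oxide eNose: either a
body-odor sample (ear / armpit / lower back), a control-odorant sample, or a
housekeeping record (baseline, clean cycle).  Each sensor reports the
conductivity ratio G0/G; its *endpoint* is the value at the end of the 50 s
measurement phase.  Two devices run simultaneously, and the analysis fuses
their endpoints into one 20-feature vector per sample (device 1 sensors 1-10,
then device 2 sensors 1-10).

The central exchange object is :class:`EndpointTable`, a thin validated
wrapper around a tidy :class:`pandas.DataFrame` in *wide* form: one row per
fused sample, metadata columns followed by ``d{device}_s{sensor}`` feature
columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: Controlled vocabulary for body regions (lower-case).
REGIONS = ("ear", "armpit", "back")

#: Sample kinds.  Only ``body`` and ``fresh_control`` enter the analysis;
#: the remaining kinds are carried through as optional metadata records.
SAMPLE_KINDS = ("body", "fresh_control", "overnight_control", "baseline", "clean_cycle")

#: PEN3 sensor names, in array order (manufacturer designations).
SENSOR_NAMES = ("W1C", "W5S", "W3C", "W6S", "W5C", "W1S", "W1W", "W2S", "W2W", "W3S")

META_COLUMNS = ("participant", "day", "kind", "region", "replicate")


class SchemaError(ValueError):
    """A table or file does not conform to the canonical schema."""


class ValidationError(ValueError):
    """Schema-conformant data violates a semantic invariant."""


def feature_columns(n_devices: int = 2, sensors_per_device: int = 10) -> list[str]:
    """Canonical fused feature column names: device 1 sensors, then device 2."""
    return [
        f"d{dev}_s{sen}"
        for dev in range(1, n_devices + 1)
        for sen in range(1, sensors_per_device + 1)
    ]


@dataclass
class MeasurementRecord:
    """One eNose measurement from a single device.

    ``endpoints`` holds the per-sensor conductivity-ratio endpoints; if the
    record carries a raw time series instead, ``series`` is a
    ``(n_sensors, T)`` array and ``endpoints`` may be ``None`` until
    :func:`odorid.io.extract_endpoints` condenses it.
    """

    participant: str
    day: int
    kind: str
    device: int
    region: Optional[str] = None
    replicate: Optional[int] = None
    endpoints: Optional[np.ndarray] = None
    series: Optional[np.ndarray] = None
    times: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.kind not in SAMPLE_KINDS:
            raise ValidationError(f"unknown sample kind {self.kind!r}")
        if self.kind == "body":
            if self.region not in REGIONS:
                raise ValidationError(
                    f"body record needs a region in {REGIONS}, got {self.region!r}"
                )
            if self.replicate is None or self.replicate < 1:
                raise ValidationError("body record needs replicate >= 1")
        else:
            if self.region is not None:
                raise ValidationError(f"{self.kind} record must not carry a region")
        if self.endpoints is not None:
            self.endpoints = np.asarray(self.endpoints, dtype=float)
            if not np.all(self.endpoints > 0):
                raise ValidationError("endpoints must be strictly positive (G0/G ratio)")
        if self.series is not None:
            self.series = np.asarray(self.series, dtype=float)
            if self.series.ndim != 2:
                raise ValidationError("series must be a (n_sensors, T) array")


@dataclass
class EndpointTable:
    """Tidy wide-form table of fused endpoint vectors.

    ``frame`` columns: ``participant, day, kind, region, replicate`` followed
    by the fused feature columns (``d1_s1`` ... ``d2_s10`` by default).
    ``region`` is ``None`` and ``replicate`` is NA for non-body rows.
    """

    frame: pd.DataFrame
    features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.features:
            self.features = [c for c in self.frame.columns if c not in META_COLUMNS]
        self.validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_rows(cls, rows: Iterable[dict], features: Sequence[str]) -> "EndpointTable":
        frame = pd.DataFrame(list(rows), columns=list(META_COLUMNS) + list(features))
        return cls(frame=frame, features=list(features))

    @classmethod
    def empty(cls, features: Sequence[str] | None = None) -> "EndpointTable":
        feats = list(features) if features is not None else feature_columns()
        frame = pd.DataFrame(columns=list(META_COLUMNS) + feats)
        return cls(frame=frame, features=feats)

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"missing metadata columns: {missing}")
        missing = [c for c in self.features if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"missing feature columns: {missing}")
        frame = self.frame
        if len(frame) == 0:
            self._normalize_dtypes()
            return
        bad_kind = set(frame["kind"]) - set(SAMPLE_KINDS)
        if bad_kind:
            raise ValidationError(f"unknown sample kinds: {sorted(bad_kind)}")
        self._normalize_dtypes()
        frame = self.frame
        values = frame[self.features].to_numpy(dtype=float)
        if np.isnan(values).any():
            row = int(np.argwhere(np.isnan(values))[0, 0])
            raise ValidationError(f"missing endpoint value in row {row}")
        if not (values > 0).all():
            row = int(np.argwhere(values <= 0)[0, 0])
            raise ValidationError(f"non-positive endpoint in row {row}")
        body = frame[frame["kind"] == "body"]
        if body["region"].isna().any():
            raise ValidationError("body rows must carry a region")
        bad_region = set(body["region"].dropna()) - set(REGIONS)
        if bad_region:
            raise ValidationError(f"unknown regions: {sorted(bad_region)}")
        if body["replicate"].isna().any():
            raise ValidationError("body rows must carry a replicate index")
        nonbody = frame[frame["kind"] != "body"]
        if len(nonbody) and nonbody["region"].notna().any():
            raise ValidationError("non-body rows must not carry a region")
        key_cols = ["participant", "day", "kind", "region", "replicate"]
        keys = frame[key_cols].astype(object).where(frame[key_cols].notna(), "")
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise ValidationError(f"duplicated sample key: {dup}")

    def _normalize_dtypes(self) -> None:
        frame = self.frame
        frame["participant"] = frame["participant"].astype(str) if len(frame) else frame[
            "participant"
        ]
        if len(frame):
            frame["day"] = frame["day"].astype(int)
        frame["region"] = frame["region"].where(
            frame["region"].notna() & (frame["region"].astype(object) != ""), None
        )
        frame["replicate"] = pd.array(
            [None if pd.isna(v) or v == "" else int(v) for v in frame["replicate"]],
            dtype="Int64",
        )

    # -- convenience ------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def body_only(self) -> "EndpointTable":
        return EndpointTable(
            frame=self.frame[self.frame["kind"] == "body"].reset_index(drop=True).copy(),
            features=list(self.features),
        )

    def matrix(self) -> np.ndarray:
        """Feature matrix (n_samples, n_features), row order preserved."""
        return self.frame[self.features].to_numpy(dtype=float)

    def labels(self) -> np.ndarray:
        """Participant labels aligned with :meth:`matrix` rows."""
        return self.frame["participant"].to_numpy(dtype=object)

    def copy(self) -> "EndpointTable":
        return EndpointTable(frame=self.frame.copy(), features=list(self.features))

    def equals(self, other: "EndpointTable", rtol: float = 0.0, atol: float = 0.0) -> bool:
        """Field-by-field equality; feature values compared numerically."""
        if self.features != other.features or len(self) != len(other):
            return False
        a, b = self.frame.reset_index(drop=True), other.frame.reset_index(drop=True)
        meta = list(META_COLUMNS)
        if not a[meta].astype(object).where(a[meta].notna(), None).equals(
            b[meta].astype(object).where(b[meta].notna(), None)
        ):
            return False
        return np.allclose(
            a[self.features].to_numpy(float), b[self.features].to_numpy(float),
            rtol=rtol, atol=atol,
        )
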