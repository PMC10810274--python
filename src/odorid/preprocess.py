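"""Drift correction and table shaping ahead of classification.

Metal-oxide sensor responses drift across sessions (and body odor itself
drifts too).  The correction implemented here divides every body sample's
fused endpoint vector, element-wise and device-aligned, by the endpoint
vector of the *same participant-day's* fresh control-odorant measurement.
Any multiplicative day x device x sensor factor shared by body and control
measurements cancels exactly — which is precisely why the correction removes
instrument drift when body and control drift are fully coupled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .datamodel import EndpointTable, ValidationError

DRIFT_MODES = ("none", "fresh_control_division")


@dataclass(frozen=True)
class DriftCorrectionSpec:
    """How (and whether) to correct for drift.

    ``mode="fresh_control_division"`` divides each body vector by its
    matched fresh control, keyed on (participant, day); ``mode="none"``
    passes body rows through unchanged.
    """

    mode: str = "fresh_control_division"

    def __post_init__(self) -> None:
        if self.mode not in DRIFT_MODES:
            raise ValueError(f"mode must be one of {DRIFT_MODES}, got {self.mode!r}")


def drift_correct(table: EndpointTable, spec: DriftCorrectionSpec) -> EndpointTable:
    """Apply drift correction; output contains body rows only.

    With control division, every (participant, day) holding body rows must
    hold exactly one fresh_control row with strictly positive endpoints.
    """
    body = table.body_only()
    if spec.mode == "none":
        return body
    frame = table.frame
    controls = frame[frame["kind"] == "fresh_control"]
    control_map = {}
    for _, row in controls.iterrows():
        key = (row["participant"], int(row["day"]))
        if key in control_map:
            raise ValidationError(f"duplicate fresh control for participant={key[0]} day={key[1]}")
        vec = row[table.features].to_numpy(dtype=float)
        if not np.all(vec > 0):
            raise ValidationError(
                f"non-positive control endpoint for participant={key[0]} day={key[1]}"
            )
        control_map[key] = vec
    out = body.frame.copy()
    values = out[body.features].to_numpy(dtype=float)
    for i, (_, row) in enumerate(out.iterrows()):
        key = (row["participant"], int(row["day"]))
        if key not in control_map:
            raise ValidationError(
                f"missing fresh control for participant={key[0]} day={key[1]}"
            )
        values[i] = values[i] / control_map[key]
    out[body.features] = values
    return EndpointTable(frame=out, features=list(body.features))


def subset(
    table: EndpointTable,
    days: Optional[Iterable[int]] = None,
    regions: Optional[Iterable[str]] = None,
    kinds: Optional[Iterable[str]] = None,
) -> EndpointTable:
    """Filtered copy of *table*; ``None`` keeps a dimension unrestricted.

    Raises on an empty selection — an empty table downstream is always a
    design mistake, never a valid analysis input.
    """
    frame = table.frame
    mask = np.ones(len(frame), dtype=bool)
    if days is not None:
        mask &= frame["day"].isin(set(int(d) for d in days)).to_numpy()
    if regions is not None:
        mask &= frame["region"].isin(set(regions)).to_numpy()
    if kinds is not None:
        mask &= frame["kind"].isin(set(kinds)).to_numpy()
    if not mask.any():
        raise ValidationError(
            f"empty selection (days={days}, regions={regions}, kinds={kinds})"
        )
    return EndpointTable(frame=frame[mask].reset_index(drop=True).copy(),
                         features=list(table.features))
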