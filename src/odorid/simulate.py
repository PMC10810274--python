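"""Synthetic eNose cohort generator.

Emulates the sampling design of the study the pipeline targets: a cohort of
participants measured on consecutive days, several body regions sampled a few
times each per day by two 10-sensor devices running simultaneously, plus one
fresh control-odorant measurement per participant-day used for drift
correction.

Generative model (all terms multiplicative and log-normal, so endpoints are
strictly positive conductivity ratios and control division is well defined)::

    control(p, d, dev, s) = B_s * g(dev, s) * D(d, dev, s) * eps
    body(p, d, r, rep, dev, s) = B_s * g(dev, s) * D(d, dev, s)**kappa
                                 * exp(I(p, d, dev, s))
                                 * S(p, r, s) * J(p, r, d, s) * eps

where ``B`` is the per-sensor baseline endpoint, ``g`` a fixed per-device
gain, ``D`` the day x device drift factor shared with the control, ``S`` the
participant's region signature, ``J`` its day-to-day jitter, ``eps``
per-measurement replicate noise, and ``I`` an idiosyncratic drift term of
scale ``(1 - min(kappa, 1)) * drift_scale``.  The coupling exponent
``kappa`` governs how faithfully body-sample drift tracks control-sample
drift: at ``kappa = 1`` fresh-control division removes drift exactly; at
``kappa < 1`` correction helps only partially and can even hurt.

Randomness is organised as one global seed with per-record streams derived
deterministically from record identity, so generating fewer days never
changes the records of earlier days.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .datamodel import EndpointTable, MeasurementRecord, REGIONS, feature_columns

#: Nominal per-sensor endpoints (G0/G) for the 10-sensor array under a weak
#: body-odor headspace: most sensors rise modestly above the clean-air value
#: of 1; sensor 2 (W5S) responds with a negative signal, below 1.
DEFAULT_BASELINE = (1.6, 0.55, 1.3, 2.2, 1.2, 2.0, 2.6, 1.8, 1.9, 1.15)

_STREAM = {
    "device_gain": 1,
    "drift": 2,
    "signature": 3,
    "jitter": 4,
    "idiosyncratic": 5,
    "noise": 6,
    "tau": 7,
}
_KIND_CODE = {"body": 0, "fresh_control": 1, "overnight_control": 2}


@dataclass(frozen=True)
class CohortConfig:
    """Study design and noise regime of a synthetic cohort.

    All ``*_scale`` parameters are log-scales (standard deviations of the
    Gaussian logs of multiplicative factors); 0 switches the term off.
    ``signature_scale`` and ``signature_day_jitter`` may be a single float or
    a per-region mapping — region-specific jitter is the stability knob that
    makes one odor source more day-stable than another.
    """

    n_participants: int = 12
    n_days: int = 5
    regions: tuple[str, ...] = REGIONS
    replicates_per_region_day: int = 3
    n_devices: int = 2
    sensors_per_device: int = 10
    signature_scale: float | Mapping[str, float] = 0.25
    signature_day_jitter: float | Mapping[str, float] = field(
        default_factory=lambda: {"ear": 0.05, "armpit": 0.10, "back": 0.12}
    )
    drift_scale: float = 0.30
    drift_coupling: float = 1.0  # kappa
    replicate_noise_scale: float = 0.05
    device_gain_scale: float = 0.10
    baseline_level: tuple[float, ...] = DEFAULT_BASELINE
    response_tau_s: float = 8.0
    include_overnight_control: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need n_participants >= 2 for any classification task")
        if min(self.n_days, self.replicates_per_region_day, self.n_devices,
               self.sensors_per_device) < 1:
            raise ValueError("counts must be >= 1")
        if self.drift_coupling < 0:
            raise ValueError("drift coupling kappa must be >= 0")
        for name in ("drift_scale", "replicate_noise_scale", "device_gain_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for region in self.regions:
            if self.scale_for(region, "signature") < 0 or self.scale_for(region, "jitter") < 0:
                raise ValueError("signature scales must be >= 0")
        if len(self.baseline_level) != self.sensors_per_device:
            raise ValueError("baseline_level must have one entry per sensor")
        if any(b <= 0 for b in self.baseline_level):
            raise ValueError("baseline endpoints must be strictly positive")
        if self.response_tau_s <= 0:
            raise ValueError("response time constant tau must be > 0")

    def scale_for(self, region: str, which: str) -> float:
        value = self.signature_scale if which == "signature" else self.signature_day_jitter
        if isinstance(value, Mapping):
            return float(value.get(region, 0.0))
        return float(value)

    @property
    def n_features(self) -> int:
        return self.n_devices * self.sensors_per_device

    def participant_ids(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_participants)]


@dataclass
class GroundTruth:
    """Realized latent factors, sufficient to reconstruct noiseless endpoints."""

    baseline: np.ndarray  # (sensors,)
    device_gain: np.ndarray  # (devices, sensors)
    drift: np.ndarray  # (days, devices, sensors)
    signatures: dict  # (participant, region) -> (sensors,)
    jitter: dict  # (participant, region, day) -> (sensors,)
    idiosyncratic: dict  # (participant, day) -> (devices, sensors) log-drift

    def expected_body(self, config: CohortConfig, participant: str, day: int,
                      region: str) -> np.ndarray:
        """Noiseless fused body endpoint vector (no replicate noise)."""
        kappa = config.drift_coupling
        parts = []
        for dev in range(config.n_devices):
            parts.append(
                self.baseline
                * self.device_gain[dev]
                * self.drift[day - 1, dev] ** kappa
                * np.exp(self.idiosyncratic[(participant, day)][dev])
                * self.signatures[(participant, region)]
                * self.jitter[(participant, region, day)]
            )
        return np.concatenate(parts)

    def expected_control(self, config: CohortConfig, day: int) -> np.ndarray:
        parts = [
            self.baseline * self.device_gain[dev] * self.drift[day - 1, dev]
            for dev in range(config.n_devices)
        ]
        return np.concatenate(parts)


def _rng(config: CohortConfig, stream: str, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM[stream], *key]))


def _lognormal(rng: np.random.Generator, scale: float, size: int) -> np.ndarray:
    if scale == 0:
        return np.ones(size)
    return np.exp(rng.normal(0.0, scale, size=size))


def _draw_ground_truth(config: CohortConfig) -> GroundTruth:
    n_s = config.sensors_per_device
    gain = np.ones((config.n_devices, n_s))
    for dev in range(1, config.n_devices):  # device 1 is the reference gain
        gain[dev] = _lognormal(_rng(config, "device_gain", dev), config.device_gain_scale, n_s)
    drift = np.stack(
        [
            np.stack(
                [
                    _lognormal(_rng(config, "drift", day, dev), config.drift_scale, n_s)
                    for dev in range(config.n_devices)
                ]
            )
            for day in range(1, config.n_days + 1)
        ]
    )
    signatures, jitter, idio = {}, {}, {}
    idio_scale = (1.0 - min(config.drift_coupling, 1.0)) * config.drift_scale
    for p_idx, pid in enumerate(config.participant_ids()):
        for r_idx, region in enumerate(config.regions):
            signatures[(pid, region)] = _lognormal(
                _rng(config, "signature", p_idx, r_idx),
                config.scale_for(region, "signature"), n_s,
            )
            for day in range(1, config.n_days + 1):
                jitter[(pid, region, day)] = _lognormal(
                    _rng(config, "jitter", p_idx, r_idx, day),
                    config.scale_for(region, "jitter"), n_s,
                )
        for day in range(1, config.n_days + 1):
            rng = _rng(config, "idiosyncratic", p_idx, day)
            idio[(pid, day)] = (
                rng.normal(0.0, idio_scale, size=(config.n_devices, n_s))
                if idio_scale > 0
                else np.zeros((config.n_devices, n_s))
            )
    return GroundTruth(
        baseline=np.asarray(config.baseline_level, dtype=float),
        device_gain=gain, drift=drift,
        signatures=signatures, jitter=jitter, idiosyncratic=idio,
    )


def _measurement_noise(config: CohortConfig, p_idx: int, day: int, kind: str,
                       r_idx: int, rep: int, dev: int) -> np.ndarray:
    rng = _rng(config, "noise", p_idx, day, _KIND_CODE[kind], r_idx, rep, dev)
    return _lognormal(rng, config.replicate_noise_scale, config.sensors_per_device)


def simulate_cohort(config: CohortConfig) -> tuple[EndpointTable, GroundTruth]:
    """Generate the full endpoint table plus the latent ground truth.

    Per participant-day the table holds ``len(regions) * replicates`` body
    rows and exactly one fused fresh-control row (optionally an overnight
    control, unused by the pipeline).
    """
    truth = _draw_ground_truth(config)
    features = feature_columns(config.n_devices, config.sensors_per_device)
    rows = []
    for p_idx, pid in enumerate(config.participant_ids()):
        for day in range(1, config.n_days + 1):
            controls = ["fresh_control"]
            if config.include_overnight_control:
                controls.append("overnight_control")
            for kind in controls:
                vec = np.concatenate(
                    [
                        truth.baseline * truth.device_gain[dev]
                        * truth.drift[day - 1, dev]
                        * _measurement_noise(config, p_idx, day, kind, 0, 0, dev)
                        for dev in range(config.n_devices)
                    ]
                )
                rows.append(_row(pid, day, kind, None, None, features, vec))
            for r_idx, region in enumerate(config.regions):
                base = truth.expected_body(config, pid, day, region)
                n_s = config.sensors_per_device
                for rep in range(1, config.replicates_per_region_day + 1):
                    noise = np.concatenate(
                        [
                            _measurement_noise(config, p_idx, day, "body", r_idx, rep, dev)
                            for dev in range(config.n_devices)
                        ]
                    )
                    rows.append(_row(pid, day, "body", region, rep, features, base * noise))
    table = EndpointTable.from_rows(rows, features)
    return table, truth


def _row(pid, day, kind, region, replicate, features, vec) -> dict:
    row = {"participant": pid, "day": day, "kind": kind,
           "region": region, "replicate": replicate}
    row.update(dict(zip(features, vec)))
    return row


def simulate_time_series(
    config: CohortConfig,
    duration_s: float = 50.0,
    rate_hz: float = 1.0,
    participants: Optional[Sequence[str]] = None,
    days: Optional[Sequence[int]] = None,
) -> list[MeasurementRecord]:
    """Generate raw per-device measurement records with 10-channel series.

    Each channel relaxes exponentially from the clean-air value 1 toward its
    endpoint ``E``: ``G(t) = 1 + (E - 1) * (1 - exp(-t / tau))``.  The final
    sample therefore differs from ``E`` by ``(E - 1) * exp(-duration / tau)``,
    which is the recovery tolerance of endpoint extraction.  Sensors with
    ``E < 1`` (the negative-signal sensor) relax downward.
    """
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    if rate_hz <= 0:
        raise ValueError("sampling rate must be > 0")
    tau = config.response_tau_s
    table, truth = simulate_cohort(config)
    keep_p = set(participants) if participants is not None else None
    keep_d = set(days) if days is not None else None
    dt = 1.0 / rate_hz
    times = np.arange(dt, duration_s + dt / 2, dt)
    records = []
    n_s = config.sensors_per_device
    for _, row in table.frame.iterrows():
        if keep_p is not None and row["participant"] not in keep_p:
            continue
        if keep_d is not None and row["day"] not in keep_d:
            continue
        for dev in range(1, config.n_devices + 1):
            cols = [f"d{dev}_s{s}" for s in range(1, n_s + 1)]
            endpoints = row[cols].to_numpy(dtype=float)
            series = 1.0 + (endpoints[:, None] - 1.0) * (1.0 - np.exp(-times[None, :] / tau))
            records.append(
                MeasurementRecord(
                    participant=row["participant"], day=int(row["day"]),
                    kind=row["kind"], device=dev,
                    region=row["region"] if row["kind"] == "body" else None,
                    replicate=int(row["replicate"]) if row["kind"] == "body" else None,
                    series=series, times=times.copy(),
                )
            )
    return records


# -- presets and config files --------------------------------------------


def strong_signal_config(seed: int = 0, **overrides) -> CohortConfig:
    """Strong-signature, low-noise regime: participants well separated,
    day-to-day jitter small, drift fully shared with the control
    (``kappa = 1``) so fresh-control division removes it exactly."""
    params = dict(
        signature_scale=0.4,
        signature_day_jitter=0.02,
        replicate_noise_scale=0.03,
        drift_scale=0.30,
        drift_coupling=1.0,
        seed=seed,
    )
    params.update(overrides)
    return CohortConfig(**params)


def null_config(seed: int = 0, **overrides) -> CohortConfig:
    """Signature-free regime: endpoints carry no participant information, so
    every identification scheme should perform at chance (1 / n_participants)."""
    params = dict(signature_scale=0.0, signature_day_jitter=0.0, seed=seed)
    params.update(overrides)
    return CohortConfig(**params)


def config_from_file(path: str | Path, **overrides) -> CohortConfig:
    """Load a :class:`CohortConfig` from a YAML or JSON mapping."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    for key in ("regions", "baseline_level"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    data.update(overrides)
    return CohortConfig(**data)


def config_to_dict(config: CohortConfig) -> dict:
    data = asdict(config)
    data["regions"] = list(data["regions"])
    data["baseline_level"] = list(data["baseline_level"])
    if isinstance(data["signature_day_jitter"], Mapping):
        data["signature_day_jitter"] = dict(data["signature_day_jitter"])
    return data
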