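import numpy as np
import pytest

from odorid import (
    CohortConfig,
    DriftCorrectionSpec,
    drift_correct,
    simulate_cohort,
    strong_signal_config,
    subset,
)


@pytest.fixture(scope="session")
def default_cohort():
    """Full 12 x 5 x 3 x 3 cohort at the default noise regime."""
    return simulate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def strong_cohort():
    """Strong-signature, low-noise cohort (kappa = 1)."""
    return simulate_cohort(strong_signal_config(seed=7))


@pytest.fixture(scope="session")
def strong_ear_day1(strong_cohort):
    """Drift-corrected day-1 ear table of the strong cohort (36 samples)."""
    table, _ = strong_cohort
    body = drift_correct(table, DriftCorrectionSpec())
    return subset(body, days=[1], regions=["ear"])


@pytest.fixture(scope="session")
def tiny_config():
    """Small, fast cohort for structural tests."""
    return CohortConfig(n_participants=4, n_days=2, replicates_per_region_day=2,
                        regions=("ear", "armpit"), seed=11)


def noiseless_config(**overrides):
    params = dict(signature_scale=0.5, signature_day_jitter=0.0, drift_scale=0.0,
                  replicate_noise_scale=0.0, device_gain_scale=0.0,
                  drift_coupling=1.0, seed=5)
    params.update(overrides)
    return CohortConfig(**params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
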