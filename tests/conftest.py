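import numpy as np
import pytest

from gliopid import (
    HazardCoefficients,
    SimulationConfig,
    VolumeTrajectory,
    simulate_cohort,
    simulate_survival,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def linear_trajectory():
    """Noise-free control subject: 1 mL per 3 months through both windows."""
    return VolumeTrajectory("lin", [-6, -3, 0, 3, 6], [10, 11, 12, 13, 14])


@pytest.fixture
def stabilized_trajectory():
    """Noise-free treated subject: growth flattened at treatment start."""
    return VolumeTrajectory("flat", [-6, -3, 0, 3, 6], [10, 11, 12, 12, 12])


@pytest.fixture
def noiseless_config():
    return SimulationConfig(
        n_subjects=2,
        randomization_ratio=(1, 1),
        baseline_sd=0.0,
        noise_sd=0.0,
        scan_jitter_sd=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The default 40/40 two-arm cohort, shared across tests."""
    return simulate_cohort(SimulationConfig(seed=11))


def make_survival_cohort(
    seed,
    n=400,
    betas=(0.0, 0.05, 0.0),
    h0=0.05,
    followup=24.0,
    baseline_sd=3.0,
):
    """Cohort with survival outcomes drawn from the PID hazard.

    The wide 3-mL baseline SD gives the burden covariate enough cross-subject
    spread for informative coefficient recovery.
    """
    config = SimulationConfig(
        n_subjects=n,
        randomization_ratio=(n // 2, n - n // 2),
        baseline_sd=baseline_sd,
        seed=seed,
    )
    cohort = simulate_cohort(config)
    coef = HazardCoefficients(*betas, h0=h0)
    for i, rec in enumerate(cohort):
        stream = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(10_000 + i,))
        )
        rec.survival = simulate_survival(rec.trajectory, coef, followup, stream)
    return cohort
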