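import numpy as np
import pytest

from octadme.synth import (
    AngiogramParams,
    CohortParams,
    Trajectory,
    default_cohort_params,
    simulate_angiogram,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def default_angiogram():
    """One generator angiogram + truth at default parameters (seed 3)."""
    return simulate_angiogram(AngiogramParams(seed=3))


@pytest.fixture(scope="session")
def noisefree_angiogram():
    return simulate_angiogram(AngiogramParams(seed=5, noise_sd=0.0))


@pytest.fixture(scope="session")
def small_cohort():
    """A default 48-patient cohort (seed 1)."""
    return simulate_cohort(default_cohort_params("vd_ge_01", seed=1))


def noiseless_cohort_params(group_var: str = "vd_ge_01", seed: int = 0, **overrides):
    """Cohort parameters with all randomness in the outcomes switched off."""
    return default_cohort_params(
        group_var,
        seed=seed,
        sd_patient_intercept_bcva=0.0,
        sd_patient_intercept_crt=0.0,
        sd_residual_bcva=0.0,
        sd_residual_crt=0.0,
        derive_residual_from_baseline_sd=False,
        **overrides,
    )


@pytest.fixture(scope="session")
def noiseless_cohort():
    return simulate_cohort(noiseless_cohort_params(seed=2))


def flat_cohort_params(seed: int = 0, *, sd_residual: float = 5.0, **overrides):
    """Cohort with identical trajectories in both subgroups.

    With no group-level trajectory contrast, the only structure in the
    outcomes is whatever ``bcva_effects`` / ``crt_effects`` inject, which
    makes these parameters the right null base for effect-recovery and
    type-I-error simulations.
    """
    flat = Trajectory(71.5, 0.0, 390.0, 0.0, (0.0,) * 7, (0.0,) * 7)
    return default_cohort_params(
        "vd_ge_01",
        seed=seed,
        trajectories={True: flat, False: flat},
        derive_residual_from_baseline_sd=False,
        sd_patient_intercept_bcva=6.0,
        sd_patient_intercept_crt=60.0,
        sd_residual_bcva=sd_residual,
        sd_residual_crt=8.0 * sd_residual,
        **overrides,
    )


def make_line_mask(length=100, shape=(200, 200), row=100, col0=50):
    mask = np.zeros(shape, dtype=bool)
    mask[row, col0:col0 + length] = True
    return mask
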