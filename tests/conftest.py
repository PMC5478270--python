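import numpy as np
import pytest

from threatflow.synthio import (
    FmriSimConfig,
    MegSimConfig,
    make_fmri_cohort,
    make_meg_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_fmri_cohort():
    """Tiny 3-subject cohort shared by read-only tests."""
    cfg = FmriSimConfig(
        n_subjects=3, grid_shape=(10, 10, 10), run_length_s=240.0,
        n_runs=2, delta_rho=0.2, seed=99,
    )
    subjects, truth = make_fmri_cohort(cfg)
    return cfg, subjects, truth


@pytest.fixture(scope="session")
def small_meg_cohort():
    """3-subject MEG cohort with a known alpha modulation."""
    cfg = MegSimConfig(
        n_subjects=3, trials_per_condition=24, alpha_mod=0.8,
        iaf_values=[10.0, 8.5, 11.0], seed=77,
    )
    subjects, model, truth = make_meg_cohort(cfg)
    return cfg, subjects, model, truth
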