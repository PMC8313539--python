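import numpy as np
import pytest

from ddmix.params import TrialVariability, WienerParams, canonical_design
from ddmix.synthetic import simulate_dataset


@pytest.fixture(scope="session")
def canonical():
    return canonical_design()


@pytest.fixture(scope="session")
def slow_cell(canonical):
    """Highest-accuracy design cell (speed 5, contrast 5): no guessing."""
    cond = canonical.condition(5, 5)
    return cond.wiener, cond.var


@pytest.fixture(scope="session")
def small_dataset(canonical):
    """One subject, 50 trials/cell: quick structural checks."""
    return simulate_dataset(
        canonical, n_subjects=1, n_trials_per_cell=50, seed=5, between_subject_sd=0.0
    )


@pytest.fixture(scope="session")
def study_dataset(canonical):
    """Full-scale study simulation: 20 subjects x 5000 trials, all
    generated from the canonical design parameters.  Shared by the
    benchmark and chance-accuracy tests."""
    return simulate_dataset(
        canonical, n_subjects=20, n_trials_per_cell=200, seed=1,
        between_subject_sd=0.0,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
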