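import numpy as np
import pytest

from avotraj import (
    ModelSpec,
    build_design,
    fit_multistart,
    simulate_cohort,
    study2_config,
    to_matrix,
)


@pytest.fixture(scope="session")
def study2_cohort():
    return simulate_cohort(study2_config(), seed=1)


@pytest.fixture(scope="session")
def study2_matrix(study2_cohort):
    Y, ids = to_matrix(study2_cohort)
    return Y


@pytest.fixture(scope="session")
def study2_fit(study2_matrix):
    """One fitted 4-class Study-2 solution, shared across tests."""
    design = build_design(5)
    spec = ModelSpec(K=4, random_factors=(0, 1), n_starts=50, n_final_starts=5, seed=1)
    return fit_multistart(study2_matrix, design, spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
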