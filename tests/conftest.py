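import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dffglu.dff import profile_matrix
from dffglu.simulate import CohortConfig, synthesize_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_cohort():
    """Fast cohort: 20 + 40 patients, 2 days of data each."""
    return synthesize_cohort(CohortConfig(n_lada=20, n_t2dm=40, days=2, seed=7))


@pytest.fixture(scope="session")
def small_F(small_cohort):
    return profile_matrix(small_cohort.traces, 2, 130)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-sized cohort: 60 LADA-like + 120 T2DM-like, 7 days."""
    return synthesize_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def default_F(default_cohort):
    return profile_matrix(default_cohort.traces, 2, 130)
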