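import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pfpmi import GeneratorConfig, load_table1_fixture, simulate_cohort

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def cohort_full():
    """Default full-range synthetic cohort (n=24, PMI 16-170 h)."""
    return simulate_cohort(GeneratorConfig(n_samples=24, seed=1))


@pytest.fixture(scope="session")
def cohort_restricted():
    """Default synthetic cohort restricted to the linear regime (16-100 h)."""
    return simulate_cohort(GeneratorConfig(n_samples=24, pmi_range=(16, 100), seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
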