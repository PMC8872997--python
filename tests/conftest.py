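import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with all planted structure, shared across tests."""
    from asymlink import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(n_individuals=2500, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """Outlier-free cohort: every row is a complete case."""
    from asymlink import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(n_individuals=2000, seed=7, outlier_rate=0.0)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_ai(clean_cohort):
    from asymlink import prepare_asymmetry_matrix

    return prepare_asymmetry_matrix(clean_cohort, include_sex=True)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
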