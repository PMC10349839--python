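import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from gazefield import DisplayConfig, build_catalog
from gazefield.simulate import ObserverParams, synthetic_roi_map


@pytest.fixture(scope="session")
def cfg() -> DisplayConfig:
    return DisplayConfig.default()


@pytest.fixture(scope="session")
def roimap(cfg):
    return synthetic_roi_map("img01", cfg)


@pytest.fixture(scope="session")
def catalog():
    return build_catalog()


@pytest.fixture(scope="session")
def small_cohort():
    """A 2+2-participant cohort shared across tests (deterministic)."""
    from gazefield.simulate import simulate_cohort

    return simulate_cohort(n_experts=2, n_novices=2, master_seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
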