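import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=200,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from fusefid.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def control_sim():
    """Small seeded control cohort shared across read-only tests."""
    cfg = SimulationConfig(seed=11, n_embryos=4)
    datasets, truth = simulate(cfg)
    return cfg, datasets, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
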