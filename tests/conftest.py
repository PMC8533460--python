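import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nanoclem.pipeline import PipelineConfig, run_pipeline
from nanoclem.simulate import SimulationConfig, simulate_pair

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pair100():
    """One 100-domain paired fixture shared by the slower integration tests."""
    config = SimulationConfig(seed=1, n_domains=100)
    tirf, esem, truth = simulate_pair(config)
    return config, tirf, esem, truth


@pytest.fixture(scope="session")
def pipeline100(pair100):
    config, tirf, esem, truth = pair100
    with np.errstate(all="ignore"):
        result = run_pipeline(tirf, esem, truth.fiducials, PipelineConfig())
    return config, truth, result


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
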