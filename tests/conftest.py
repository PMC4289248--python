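import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sharkpop import DemographicParams, MonteCarloSettings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def default_params():
    return DemographicParams()


@pytest.fixture
def mc_settings():
    """Full-size Monte-Carlo protocol with a fixed master seed."""
    return MonteCarloSettings(n_runs=100, master_seed=1234)


@pytest.fixture
def small_settings():
    """Cheap protocol for structural (non-calibration) checks."""
    return MonteCarloSettings(n_runs=20, master_seed=99)
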