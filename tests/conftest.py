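import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """An 8x12 plate screen with short curves, for fast structural tests."""
    from colonyscreen import SimulationConfig

    return SimulationConfig(
        rows=8,
        cols=12,
        duration=24.0,
        corruption_rate=0.0,
        noise_sd=0.0,
        bias_amplitude=0.0,
        seed=11,
    )
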