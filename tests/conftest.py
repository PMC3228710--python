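import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from emma_eog import SimulationConfig, simulate_recording

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """Half-hour default-condition simulation shared across tests."""
    cfg = SimulationConfig(hours=0.5, seed=11)
    rec, hyp, truth = simulate_recording(cfg)
    return cfg, rec, hyp, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
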