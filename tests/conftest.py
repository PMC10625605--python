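import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from neurosampler import generative as g

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tuning():
    return g.TuningModel(n_e=180, a=40.0)


@pytest.fixture(scope="session")
def world(tuning):
    """Standard hierarchical world: moderate prior coupling, ~250 input spikes."""
    return g.HierarchicalWorld(Lambda_s=0.05, U_f=5.0, tuning=tuning)


@pytest.fixture(scope="session")
def fixed_input(world):
    """One seeded feedforward input draw shared across tests."""
    return g.sample_feedforward(world, 0.0, np.random.default_rng(2024))
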