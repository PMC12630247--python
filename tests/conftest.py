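import numpy as np
import pytest

from reidpose.simulate import ScenarioConfig, simulate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scenario():
    """A separable 3-person session shared by read-only tests."""
    cfg = ScenarioConfig(K=3, n_frames=200, noise_sigma=0.5,
                         centroid_separation=10.0, seed=42)
    return simulate_session(cfg)
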