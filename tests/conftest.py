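import numpy as np
import pytest

from stemleaf.synthdata import SceneParams, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 128 px scene shared across tests."""
    return generate_scene(SceneParams(size=128, seed=7))


@pytest.fixture(scope="session")
def noisy_scene():
    return generate_scene(SceneParams(size=128, seed=7, noise_density=0.04))
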