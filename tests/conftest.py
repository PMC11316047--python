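import numpy as np
import pytest

from mitoquant.synth import SceneConfig, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_tube_scene():
    """One clean scene with tubes, reused by read-only tests."""
    cfg = SceneConfig(n_mito=6, seed=42)
    return generate_scene(cfg), cfg
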