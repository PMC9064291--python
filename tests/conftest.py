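import numpy as np
import pytest

from centriomig import SceneConfig, generate_knob_scene
from centriomig.detection import detect_spots


@pytest.fixture(scope="session")
def knob_scene():
    """One noisy knob scene shared by detection-oriented tests."""
    config = SceneConfig(seed=11)
    grid, truth = generate_knob_scene(config)
    return config, grid, truth


@pytest.fixture(scope="session")
def knob_spots(knob_scene):
    _, grid, _ = knob_scene
    return detect_spots(grid, channel="centrin")


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
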