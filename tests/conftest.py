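import numpy as np
import pytest

from smearkit.synthetic import SceneConfig, generate_dataset, generate_scene
from smearkit.taxonomy import DEFAULT_TAXONOMY


@pytest.fixture(scope="session")
def taxonomy():
    return DEFAULT_TAXONOMY


@pytest.fixture(scope="session")
def small_scene():
    """One rendered 640x480 scene with 40 cells and its ground truth."""
    cfg = SceneConfig(width=640, height=480, cells_per_image=40, seed=3)
    image, truth = generate_scene(cfg, image_id="scene0")
    return image, truth


@pytest.fixture(scope="session")
def multi_image_truth():
    """Five unrendered scenes pooled into one annotation set (~200 cells)."""
    cfg = SceneConfig(width=640, height=480, cells_per_image=40, seed=9)
    truth, _ = generate_dataset(cfg, 5, seed=9, render=False)
    return truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
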