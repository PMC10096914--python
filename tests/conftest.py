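import numpy as np
import pytest

from treecensus.synth import SceneConfig, generate_scene, scene_to_annotations


@pytest.fixture(scope="session")
def small_scene():
    """A 128 px deciduous scene with moderate crowding, shared across tests."""
    cfg = SceneConfig(width_px=128, height_px=128, pixel_size_m=0.2,
                      regime="deciduous", n_trees=15,
                      crown_radius_range_m=(0.8, 2.0), seed=7)
    raster, truth = generate_scene(cfg)
    return cfg, raster, truth


@pytest.fixture(scope="session")
def small_annotations(small_scene):
    _, _, truth = small_scene
    return scene_to_annotations(truth)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
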