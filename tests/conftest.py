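import numpy as np
import pytest

from contourdensity import ReflectanceRaster, SceneConfig, generate_mosaic, two_field_scene


@pytest.fixture(scope="session")
def mosaic_small():
    """A 256 px noise-free mosaic reused by read-only tests."""
    return generate_mosaic(SceneConfig(grid_size=256, seed=3, noise_sd=0.0))


@pytest.fixture(scope="session")
def mosaic_noisy():
    return generate_mosaic(SceneConfig(grid_size=256, seed=3))


@pytest.fixture
def two_field():
    return two_field_scene(grid_size=64)


@pytest.fixture
def random_raster():
    rng = np.random.default_rng(42)
    values = rng.uniform(0, 1, size=(40, 40))
    return ReflectanceRaster(values=values, valid_mask=np.ones((40, 40), dtype=bool))
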