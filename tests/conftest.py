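import numpy as np
import pytest

from carbonscape import SceneConfig, default_registry, generate_scene
from carbonscape.raster import GridSpec, Raster, RasterStack


@pytest.fixture(scope="session")
def small_scene():
    """A compact paired-resolution scene shared by read-only tests."""
    cfg = SceneConfig(extent_pixels_10m=(90, 90), seed=5, vi_signal_r=0.7)
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture
def grid10():
    return GridSpec(0.0, 900.0, 10.0)


def make_stack(bands: dict, pixel_size: float = 10.0) -> RasterStack:
    shape = next(iter(bands.values())).shape
    grid = GridSpec(0.0, shape[0] * pixel_size, pixel_size)
    return RasterStack({k: np.asarray(v, float) for k, v in bands.items()}, grid)


def make_raster(data, pixel_size: float = 10.0, mask=None) -> Raster:
    data = np.asarray(data, float)
    grid = GridSpec(0.0, data.shape[0] * pixel_size, pixel_size)
    return Raster(data, grid, mask=mask)
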