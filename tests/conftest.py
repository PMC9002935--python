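import functools

import numpy as np
import pytest
from skimage.draw import disk as _disk
from skimage.draw import ellipse as _ellipse

from seedshape.models import rasterize_model


@functools.lru_cache(maxsize=64)
def _cached_raster(model_id: str, height_px: int, margin_px: int):
    return rasterize_model(model_id, height_px, margin_px)


@pytest.fixture(scope="session")
def raster():
    """Session-cached model rasterizer: raster('DM5', 200, 8)."""
    return _cached_raster


@pytest.fixture()
def disk_mask():
    def make(radius=100, pad=10):
        side = 2 * (radius + pad) + 1
        mask = np.zeros((side, side), dtype=bool)
        rr, cc = _disk((side // 2, side // 2), radius, shape=mask.shape)
        mask[rr, cc] = True
        return mask
    return make


@pytest.fixture()
def ellipse_mask():
    def make(a=200, b=100, pad=10):
        mask = np.zeros((2 * (b + pad) + 1, 2 * (a + pad) + 1), dtype=bool)
        rr, cc = _ellipse(b + pad, a + pad, b, a, shape=mask.shape)
        mask[rr, cc] = True
        return mask
    return make
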