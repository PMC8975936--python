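import numpy as np
import pytest
from scipy import ndimage


@pytest.fixture
def textured_pair():
    """Factory for band-limited noise frame pairs related by a known shift.

    The base canvas is larger than the returned crop so that content shifted
    into view is real texture, not padding.
    """

    def make(dx, dy, size=100, margin=20, sigma=2.0, seed=0):
        rng = np.random.default_rng(seed)
        canvas = ndimage.gaussian_filter(
            rng.standard_normal((size + 2 * margin, size + 2 * margin)), sigma
        )
        yy, xx = np.mgrid[0:size, 0:size].astype(float)
        f0 = canvas[margin : margin + size, margin : margin + size]
        f1 = ndimage.map_coordinates(
            canvas, [yy + margin - dy, xx + margin - dx], order=3, mode="nearest"
        )
        return f0, f1

    return make


@pytest.fixture
def interior():
    """Slice selecting pixels away from image borders."""
    return slice(15, -15)
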