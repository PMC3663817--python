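import numpy as np
import pytest

from bollmark.images import BollMask, RatioImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def full_mask_ratio(pixels: np.ndarray, resolution: float = 18.0) -> RatioImage:
    """Wrap an array as a RatioImage with an all-ones mask."""
    mask = BollMask(np.ones(pixels.shape, dtype=np.uint8))
    return RatioImage(np.asarray(pixels, dtype=float), mask, resolution)


def disk_image(radius: float, shape=(128, 128), center=None, inside=1.0, outside=0.0):
    """Sharp-edged disk raster (pixel centers inside the circle)."""
    if center is None:
        center = (shape[0] / 2.0, shape[1] / 2.0)
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    d2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
    return np.where(d2 <= radius**2, inside, outside)


def normalized_gradient(img: np.ndarray) -> np.ndarray:
    from scipy import ndimage

    g = np.hypot(ndimage.sobel(img, axis=0), ndimage.sobel(img, axis=1))
    m = g.max()
    return g / m if m > 0 else g
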