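"""TIFF input/output and debug overlays."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import tifffile

from .images import ColorImage, RatioImage

logger = logging.getLogger(__name__)

__all__ = ["read_color_tiff", "write_color_tiff", "write_float_tiff", "write_overlay_png"]


def read_color_tiff(
    path: str | Path, resolution_px_per_mm: float = 18.0, bit_depth: int = 12
) -> ColorImage:
    """Read a single-image RGB TIFF.

    16-bit containers carrying 12-bit data are the native format; 8-bit
    images are accepted with a warning and promoted to the 12-bit range.
    """
    raw = tifffile.imread(str(path))
    if raw.ndim != 3 or raw.shape[2] < 3:
        raise ValueError(f"{path}: expected an H×W×3 RGB TIFF")
    arr = raw[:, :, :3].astype(np.float64)
    if raw.dtype == np.uint8:
        logger.warning("%s: 8-bit image promoted to 12-bit range", path)
        arr = arr * (4095.0 / 255.0)
    return ColorImage(arr, bit_depth=bit_depth, resolution_px_per_mm=resolution_px_per_mm)


def write_color_tiff(path: str | Path, img: ColorImage) -> None:
    """Write a color image as 16-bit TIFF (12-bit data retained)."""
    tifffile.imwrite(str(path), np.round(img.pixels).astype(np.uint16))


def write_float_tiff(path: str | Path, pixels: np.ndarray) -> None:
    """Write an intermediate image as 32-bit float TIFF for debugging."""
    tifffile.imwrite(str(path), pixels.astype(np.float32))


def write_overlay_png(path: str | Path, ratio: RatioImage, snakes) -> None:
    """RGB PNG of the ratio image with snake polygons drawn in red."""
    import imageio.v3 as iio
    from skimage.draw import polygon_perimeter

    px = ratio.pixels
    scale = px.max() or 1.0
    gray = np.clip(px / scale * 255, 0, 255).astype(np.uint8)
    rgb = np.stack([gray, gray, gray], axis=-1)
    for s in snakes:
        rr, cc = polygon_perimeter(
            np.round(s.vertices[:, 0]).astype(int),
            np.round(s.vertices[:, 1]).astype(int),
            shape=px.shape,
            clip=True,
        )
        rgb[rr, cc] = (255, 40, 40)
    iio.imwrite(str(path), rgb)
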