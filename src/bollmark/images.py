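"""Ratiometric imaging of fluorescence-illuminated cotton bolls.

A raw color photograph of a boll against a black backdrop is turned into a
background-free green/red ratio image in a fixed chain: center-weighted
median filter → 2×2 binning → two parallel branches, one building a boll
mask (single channel, Butterworth low-pass blur, fixed threshold, largest
connected component) and one dividing the green channel by the red channel
pixel-by-pixel.  Multiplying the ratio by the mask zeroes the background.

Under blue LED excitation, intact boll tissue fluoresces red (chlorophyll)
while damaged tissue fluoresces green, so the ratio image is elevated
wherever damage-related emission replaces chlorophyll emission — the
substrate every downstream detection step works on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from skimage import measure, morphology

logger = logging.getLogger(__name__)

__all__ = [
    "ColorImage",
    "MonoImage",
    "BollMask",
    "RatioImage",
    "ImagingConfig",
    "center_weighted_median",
    "bin2x2",
    "butterworth_lowpass",
    "make_boll_mask",
    "ratiometric_image",
    "process_color_image",
]


@dataclass
class ColorImage:
    """3-channel intensity image (R, G, B planes) carrying 12-bit data.

    ``pixels`` is an H×W×3 nonnegative float array; values must stay below
    ``2**bit_depth``.  ``resolution_px_per_mm`` converts pixel areas to mm².
    """

    pixels: np.ndarray
    bit_depth: int = 12
    resolution_px_per_mm: float = 18.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("ColorImage requires an H×W×3 array")
        h, w = self.pixels.shape[:2]
        if h < 2 or w < 2:
            raise ValueError("image must be at least 2×2")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("non-finite pixel values")
        if self.pixels.min() < 0:
            raise ValueError("negative pixel values")
        if self.pixels.max() >= 2**self.bit_depth:
            raise ValueError(
                f"pixel values exceed {self.bit_depth}-bit range"
            )
        if self.resolution_px_per_mm <= 0:
            raise ValueError("resolution must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def channel(self, name: str) -> "MonoImage":
        idx = {"red": 0, "green": 1, "blue": 2}[name]
        return MonoImage(self.pixels[:, :, idx], self.resolution_px_per_mm)


@dataclass
class MonoImage:
    """Single-channel real-valued image."""

    pixels: np.ndarray
    resolution_px_per_mm: float = 18.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("MonoImage requires an H×W array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("non-finite pixel values")


@dataclass
class BollMask:
    """Binary mask: 1 on the boll, 0 on background."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.pixels = arr.astype(np.uint8)


@dataclass
class RatioImage:
    """Masked pixel-wise green/red ratio image, zero on background."""

    pixels: np.ndarray
    mask: BollMask
    resolution_px_per_mm: float = 18.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.shape != self.mask.pixels.shape:
            raise ValueError("ratio/mask shape mismatch")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("non-finite ratio values")
        if np.any(self.pixels[self.mask.pixels == 0] != 0):
            raise ValueError("background ratio pixels must be 0")


def center_weighted_median(
    img: ColorImage, window: int = 3, center_weight: int = 3
) -> ColorImage:
    """Per-channel median filter in which the center pixel is counted
    ``center_weight`` times in each window's multiset.

    Borders are handled by edge replication; ``center_weight=1`` reduces to
    the plain median filter.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if center_weight < 1:
        raise ValueError("center_weight must be >= 1")
    pad = window // 2
    out = np.empty_like(img.pixels)
    for ch in range(3):
        plane = img.pixels[:, :, ch]
        padded = np.pad(plane, pad, mode="edge")
        win = sliding_window_view(padded, (window, window))
        win = win.reshape(*plane.shape, window * window)
        if center_weight > 1:
            reps = np.repeat(
                plane[:, :, None], center_weight - 1, axis=2
            )
            win = np.concatenate([win, reps], axis=2)
        out[:, :, ch] = np.median(win, axis=2)
    return replace(img, pixels=out)


def bin2x2(img: ColorImage) -> ColorImage:
    """Average each 2×2 block per channel, halving both dimensions and the
    spatial resolution.  An odd trailing row/column is dropped with a
    warning."""
    h, w = img.shape
    if h % 2 or w % 2:
        logger.warning("odd image dimension %dx%d: trailing row/col dropped", h, w)
        h -= h % 2
        w -= w % 2
    px = img.pixels[:h, :w]
    binned = px.reshape(h // 2, 2, w // 2, 2, 3).mean(axis=(1, 3))
    return ColorImage(
        binned,
        bit_depth=img.bit_depth,
        resolution_px_per_mm=img.resolution_px_per_mm / 2.0,
    )


def butterworth_lowpass(
    img: MonoImage, order: int = 2, cutoff_px: float = 10.0
) -> MonoImage:
    """Frequency-domain Butterworth low-pass blur.

    ``cutoff_px`` is the cutoff wavelength in pixels: the −3 dB frequency is
    ``f_c = 1/cutoff_px`` cycles per pixel, and the amplitude gain follows
    the standard Butterworth magnitude ``(1 + (f/f_c)^(2·order))^(−1/2)``,
    i.e. a sinusoid exactly at the cutoff comes out attenuated by 1/√2.
    DC gain is 1, so the mean intensity is preserved.
    """
    if cutoff_px <= 0:
        raise ValueError("cutoff_px must be positive")
    if not np.all(np.isfinite(img.pixels)):
        raise ValueError("non-finite input pixels")
    h, w = img.pixels.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f = np.hypot(fy, fx)
    fc = 1.0 / cutoff_px
    gain = 1.0 / np.sqrt(1.0 + (f / fc) ** (2 * order))
    blurred = np.fft.ifft2(np.fft.fft2(img.pixels) * gain).real
    return MonoImage(blurred, img.resolution_px_per_mm)


def make_boll_mask(
    blurred: MonoImage, threshold: float, min_speck_px: int = 100
) -> BollMask:
    """Threshold the blurred channel and keep the largest connected
    component; foreground specks below ``min_speck_px`` pixels (backdrop
    fluff) are discarded first.  An empty foreground yields an all-zero
    mask with a logged warning rather than an error."""
    fg = blurred.pixels >= threshold
    if not fg.any():
        logger.warning("no boll found above threshold %.3g", threshold)
        return BollMask(np.zeros_like(fg, dtype=np.uint8))
    labels = measure.label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    if counts.max() < min_speck_px:
        logger.warning("only specks (<%d px) above threshold", min_speck_px)
        return BollMask(np.zeros_like(fg, dtype=np.uint8))
    return BollMask((labels == counts.argmax()).astype(np.uint8))


def ratiometric_image(
    green: MonoImage,
    red: MonoImage,
    mask: BollMask,
    eps: float = 1.0,
) -> RatioImage:
    """Pixel-wise green/red ratio times the boll mask.

    ``eps`` guards the division (red clamped from below), so the output is
    finite everywhere and exactly zero on background.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if green.pixels.shape != red.pixels.shape or green.pixels.shape != mask.pixels.shape:
        raise ValueError("green/red/mask shape mismatch")
    ratio = mask.pixels * green.pixels / np.maximum(red.pixels, eps)
    return RatioImage(ratio, mask, green.resolution_px_per_mm)


@dataclass
class ImagingConfig:
    """Tunables of the imaging chain.

    ``mask_threshold=None`` means 5% of the blurred channel's maximum — the
    black backdrop makes the mask insensitive over a wide threshold range.
    ``eps=None`` means one least-significant unit of the bit depth (1.0).
    ``mask_erode_px`` shrinks the final mask by a small margin before the
    ratio multiplication: the blurred-threshold mask overhangs the true
    boll edge by a few pixels, and in that halo the red channel is near
    background level, making the green/red quotient spike meaninglessly.
    """

    median_window: int = 3
    median_center_weight: int = 3
    mask_channel: str = "red"
    butterworth_order: int = 2
    cutoff_px: float = 10.0
    mask_threshold: float | None = None
    mask_threshold_floor: float = 100.0
    min_speck_px: int = 100
    mask_erode_px: int = 4
    eps: float | None = None

    def __post_init__(self) -> None:
        if self.mask_channel not in ("red", "green"):
            raise ValueError("mask_channel must be 'red' or 'green'")


def process_color_image(
    img: ColorImage, cfg: ImagingConfig | None = None
) -> RatioImage:
    """Run the full imaging chain: median → binning → (mask branch ∥ ratio
    branch) → masked ratio image."""
    cfg = cfg or ImagingConfig()
    smoothed = center_weighted_median(
        img, cfg.median_window, cfg.median_center_weight
    )
    binned = bin2x2(smoothed)
    chan = binned.channel(cfg.mask_channel)
    blurred = butterworth_lowpass(chan, cfg.butterworth_order, cfg.cutoff_px)
    thr = cfg.mask_threshold
    if thr is None:
        # 5% of the blurred maximum, but never below the dark-backdrop
        # floor so a boll-free frame yields an empty mask
        thr = max(0.05 * blurred.pixels.max(), cfg.mask_threshold_floor)
    mask = make_boll_mask(blurred, thr, cfg.min_speck_px)
    if cfg.mask_erode_px > 0 and mask.pixels.any():
        eroded = ndimage.binary_erosion(
            mask.pixels, structure=morphology.disk(cfg.mask_erode_px)
        )
        mask = BollMask(eroded.astype(np.uint8))
    eps = cfg.eps if cfg.eps is not None else 1.0
    return ratiometric_image(
        binned.channel("green"), binned.channel("red"), mask, eps
    )
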