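"""Per-mark features, inclusion filters and the I1/I2 donut statistic.

A segmented mark is kept only when it looks like a plausible puncture:
large enough (area ≥ 28 px ≈ 0.09 mm² at 18 px/mm), bright enough
(integrated intensity ≥ 0.04 mm⁻²), round enough (second-moment aspect
ratio ≤ 2) and compact (convexity ≥ 0.9).  Small marks are plausibly
non-piercing insects such as spider mites; long or ragged ones mechanical
abrasion.

The discriminating statistic is the donut ratio I1/I2: the snake outline is
replaced by the equal-area circle at the mark centroid, I2 is the mean
ratio intensity inside that circle and I1 the mean inside a concentric
4-px-radius circle.  Punctures remove tissue at the center, so their
fluorescence dips there and I1/I2 falls below 1; marks of other origin are
usually center-bright with I1/I2 above 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure
from skimage.draw import polygon as draw_polygon

from .detect import SegmentedMark, Snake
from .images import RatioImage

logger = logging.getLogger(__name__)

__all__ = [
    "Mark",
    "FilterConfig",
    "area_mm2",
    "shape_features",
    "measure_mark",
    "apply_filters",
    "intensity_ratio",
]

MARK_COLUMNS = [
    "image_id",
    "mark_id",
    "label",
    "area_px",
    "area_mm2",
    "integrated_intensity",
    "aspect_ratio",
    "convexity",
    "I1",
    "I2",
    "ratio",
    "kept",
    "reject_reason",
]


@dataclass
class FilterConfig:
    """Mark inclusion thresholds.

    Boundary semantics follow the printed exclusion rules: area *below*
    28 px is excluded (28 kept), aspect ratio *greater than* 2 is excluded
    (exactly 2 kept).
    """

    min_area_px: int = 28
    min_integrated_intensity: float = 0.04
    max_aspect_ratio: float = 2.0
    min_convexity: float = 0.9
    inner_radius_px: float = 4.0

    def __post_init__(self) -> None:
        for name in (
            "min_area_px",
            "min_integrated_intensity",
            "max_aspect_ratio",
            "min_convexity",
            "inner_radius_px",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Mark:
    """A segmented fluorescent region with all measured features."""

    region: np.ndarray
    boundary: Snake | None
    centroid: tuple[float, float]
    area_px: int
    area_mm2: float
    integrated_intensity: float
    aspect_ratio: float
    convexity: float
    I1: float = np.nan
    I2: float = np.nan
    ratio: float = np.nan
    valid_ratio: bool = False
    kept: bool = False
    reject_reason: str = ""
    label: str = "unknown"
    seed: object = None


def area_mm2(area_px: int, resolution_px_per_mm: float) -> float:
    """Pixel count to mm² (28 px at 18 px/mm ≈ 0.09 mm²)."""
    if resolution_px_per_mm <= 0:
        raise ValueError("resolution must be positive")
    return area_px / resolution_px_per_mm**2


def _region_mask(region: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    r0, c0 = region.min(axis=0)
    r1, c1 = region.max(axis=0)
    mask = np.zeros((r1 - r0 + 1, c1 - c0 + 1), dtype=np.uint8)
    mask[region[:, 0] - r0, region[:, 1] - c0] = 1
    return mask, (int(r0), int(c0))


def shape_features(region: np.ndarray) -> tuple[float, float]:
    """(aspect_ratio, convexity) of a pixel region.

    Aspect ratio is major/minor axis of the region's second-moment ellipse;
    a collinear region gets aspect ratio ∞ (it can never pass the filter).
    Convexity is the pixel count of the region over the pixel count of its
    convex hull, where the hull polygon of the pixel centers is rasterized
    with the same centers-inside rule as the region itself — so convex
    digital shapes (disks, blocks, rectangles) score exactly 1 and the
    value never exceeds 1.
    """
    if len(region) < 3:
        return np.inf, 1.0
    mask, _ = _region_mask(region)
    props = measure.regionprops(mask)[0]
    minor = props.axis_minor_length
    major = props.axis_major_length
    aspect = np.inf if minor == 0 else major / minor
    try:
        hull = ConvexHull(region.astype(float))
    except QhullError:
        return float(aspect), 1.0  # collinear: aspect filter rejects it
    v = region[hull.vertices]
    rr, _cc = draw_polygon(v[:, 0], v[:, 1])
    convexity = min(1.0, len(region) / len(rr)) if len(rr) else 1.0
    return float(aspect), float(convexity)


def intensity_ratio(
    centroid: tuple[float, float],
    area_px: int,
    ratio_img: RatioImage,
    inner_radius_px: float = 4.0,
) -> tuple[float, float, float]:
    """The donut statistic (I1, I2, I1/I2).

    The mark is replaced by the circle of equal area centred at its
    centroid (radius √(area/π)); I2 averages the ratio image over pixels
    whose centers lie inside that circle, I1 over the concentric circle of
    ``inner_radius_px``.  I2 = 0 flags the mark invalid (nan ratio).
    """
    r_eq = np.sqrt(area_px / np.pi)
    img = ratio_img.pixels
    h, w = img.shape
    cr, cc = centroid

    def circle_mean(radius: float) -> float:
        r0 = max(int(np.floor(cr - radius)) - 1, 0)
        r1 = min(int(np.ceil(cr + radius)) + 1, h - 1)
        c0 = max(int(np.floor(cc - radius)) - 1, 0)
        c1 = min(int(np.ceil(cc + radius)) + 1, w - 1)
        rows = np.arange(r0, r1 + 1)[:, None]
        cols = np.arange(c0, c1 + 1)[None, :]
        inside = (rows - cr) ** 2 + (cols - cc) ** 2 <= radius**2
        if not inside.any():
            return np.nan
        return float(img[r0 : r1 + 1, c0 : c1 + 1][inside].mean())

    i2 = circle_mean(r_eq)
    i1 = circle_mean(inner_radius_px)
    if not np.isfinite(i2) or i2 == 0 or not np.isfinite(i1):
        return i1, i2, np.nan
    return i1, i2, i1 / i2


def measure_mark(
    seg: SegmentedMark,
    ratio_img: RatioImage,
    cfg: FilterConfig | None = None,
    label: str = "unknown",
) -> Mark:
    """Compute every feature of a segmented mark (filters applied later)."""
    cfg = cfg or FilterConfig()
    n = len(seg.region)
    a_mm2 = area_mm2(n, ratio_img.resolution_px_per_mm)
    if seg.degenerate or n == 0:
        return Mark(
            seg.region, seg.boundary, seg.centroid, n, a_mm2,
            0.0, np.inf, 1.0, label=label, seed=seg.seed,
        )
    total = float(ratio_img.pixels[seg.region[:, 0], seg.region[:, 1]].sum())
    integrated = total / a_mm2 if a_mm2 > 0 else 0.0
    aspect, convexity = shape_features(seg.region)
    mark = Mark(
        seg.region, seg.boundary, seg.centroid, n, a_mm2,
        integrated, aspect, convexity, label=label, seed=seg.seed,
    )
    r_eq = np.sqrt(n / np.pi)
    if r_eq > cfg.inner_radius_px:
        i1, i2, ratio = intensity_ratio(
            seg.centroid, n, ratio_img, cfg.inner_radius_px
        )
        mark.I1, mark.I2, mark.ratio = i1, i2, ratio
        mark.valid_ratio = np.isfinite(ratio)
    return mark


def apply_filters(
    marks: list[Mark], cfg: FilterConfig | None = None
) -> tuple[list[Mark], list[Mark]]:
    """Split marks into (kept, rejected); each rejected mark carries the
    first rule it failed (area → intensity → aspect → convexity)."""
    cfg = cfg or FilterConfig()
    kept: list[Mark] = []
    rejected: list[Mark] = []
    for m in marks:
        reason = ""
        if m.area_px < cfg.min_area_px:
            reason = "area"
        elif m.integrated_intensity < cfg.min_integrated_intensity:
            reason = "integrated_intensity"
        elif m.aspect_ratio > cfg.max_aspect_ratio:
            reason = "aspect_ratio"
        elif m.convexity < cfg.min_convexity:
            reason = "convexity"
        m.kept = reason == ""
        m.reject_reason = reason
        if m.kept:
            kept.append(m)
        else:
            logger.info("mark rejected: %s", reason)
            rejected.append(m)
    return kept, rejected
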