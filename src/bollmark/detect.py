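"""Candidate-mark detection and greedy-snake segmentation.

Fluorescent mark candidates are local maxima of the (rescaled) ratio image
that stand out from their 15-px-radius neighborhood; each candidate seeds a
closed 32-vertex active contour ("greedy snake") initialised as a circle
larger than the mark.  The snake energy is

    E = α·Σ|vᵢ₊₁−vᵢ|  +  β·Σ|vᵢ₊₁−2vᵢ+vᵢ₋₁|  −  γ·Σ g(vᵢ)

(stretching, bending, negative image-gradient magnitude g, cyclic indices,
bilinear sampling at real-valued vertices).  Each iteration visits the
vertices in order and greedily moves each one to the position in its small
search neighborhood that lowers the local energy, so the contour contracts
circularly until it locks onto the gradient ridge at the mark boundary.
Moves that would make the polygon self-intersect are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.draw import polygon as draw_polygon

from .images import MonoImage, RatioImage

logger = logging.getLogger(__name__)

__all__ = [
    "PeakCandidate",
    "Snake",
    "SegmentedMark",
    "SnakeParams",
    "find_local_maxima",
    "init_snake",
    "snake_energy",
    "evolve_snake_greedy",
    "snake_to_region",
    "sobel_magnitude",
    "estimate_init_radius",
]

TWELVE_BIT_MAX = 4095.0
#: ratio value mapped to the top of the 12-bit count scale for detection
RATIO_FULL_SCALE = 4.0


def ratio_to_counts(pixels):
    """Fixed mapping of green/red ratio values to 12-bit detection counts
    (ratio RATIO_FULL_SCALE -> 4095), so the printed minimum intensity
    difference of 10 counts has an image-independent meaning."""
    return np.asarray(pixels) * (TWELVE_BIT_MAX / RATIO_FULL_SCALE)


@dataclass
class PeakCandidate:
    """A local maximum of the detection image that stands out from the mean
    of its surrounding disk."""

    row: int
    col: int
    value: float
    local_mean: float


@dataclass
class Snake:
    """Closed polygon of ``n`` (row, col) vertices with its energy."""

    vertices: np.ndarray
    energy: float = np.nan
    converged: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an n×2 array")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass
class SegmentedMark:
    """Raster realization of a converged snake: the enclosed pixel set."""

    region: np.ndarray  # N×2 integer (row, col) pixel coordinates
    boundary: Snake
    centroid: tuple[float, float]
    seed: PeakCandidate | None = None
    degenerate: bool = False


@dataclass
class SnakeParams:
    """Greedy-snake evolution parameters.

    α weights stretching, β bending, γ the gradient attraction (with the
    gradient-magnitude image normalised to [0, 1]).  ``search_radius_px=1``
    gives the classic 3×3 greedy neighborhood.
    """

    alpha: float = 1.0
    beta: float = 0.5
    gamma: float = 2.0
    search_radius_px: int = 1
    max_iters: int = 200
    min_moved_fraction: float = 0.05


def _disk_kernel(radius: int) -> np.ndarray:
    r = np.arange(-radius, radius + 1)
    return (r[:, None] ** 2 + r[None, :] ** 2 <= radius**2).astype(float)


def find_local_maxima(
    ratio: RatioImage,
    min_distance_px: int = 15,
    min_difference: float = 10.0,
    neighborhood_radius_px: int = 15,
    rescale_to_12bit: bool = True,
    max_candidates: int | None = None,
    edge_margin_px: int = 8,
) -> list[PeakCandidate]:
    """Local-maximum filter for mark candidates.

    The ratio image is mapped to 12-bit counts with the fixed scale
    ``ratio_to_counts`` so the printed ``min_difference`` of 10 counts is
    dimensionally meaningful on an O(1) ratio image.  A pixel is a
    candidate when it is a neighborhood maximum inside the boll and exceeds
    the mean of the surrounding ``neighborhood_radius_px`` disk (restricted
    to the boll) by at least ``min_difference``.  Candidates are returned
    sorted by descending value; of any two closer than ``min_distance_px``
    the higher-valued one is kept, ties broken in row-major order.

    Peaks within ``edge_margin_px`` of the mask boundary are dropped: at
    the boll silhouette the green/red quotient mixes boll and backdrop
    pixels, and the mask rim itself presents a spurious intensity step a
    snake could lock onto.
    """
    img = ratio.pixels
    inside = ratio.mask.pixels.astype(bool)
    if img.max() <= 0:
        return []
    if rescale_to_12bit:
        img = ratio_to_counts(img)

    footprint = np.ones((3, 3), bool)
    seed_zone = inside
    if edge_margin_px > 0:
        dist = ndimage.distance_transform_edt(inside)
        seed_zone = inside & (dist > edge_margin_px)
    is_max = (img == ndimage.maximum_filter(img, footprint=footprint)) & seed_zone

    kernel = _disk_kernel(neighborhood_radius_px)
    num = fftconvolve(img * inside, kernel, mode="same")
    den = fftconvolve(inside.astype(float), kernel, mode="same")
    local_mean = np.where(den > 0, num / np.maximum(den, 1e-12), 0.0)

    diff_ok = (img - local_mean) >= min_difference
    rows, cols = np.nonzero(is_max & diff_ok)
    if len(rows) == 0:
        return []
    vals = img[rows, cols]
    order = np.lexsort((cols, rows, -vals))  # by value desc, then row-major
    rows, cols, vals = rows[order], cols[order], vals[order]

    kept: list[PeakCandidate] = []
    kept_rc: list[tuple[int, int]] = []
    for r, c, v in zip(rows, cols, vals):
        if all(
            (r - kr) ** 2 + (c - kc) ** 2 >= min_distance_px**2
            for kr, kc in kept_rc
        ):
            kept_rc.append((int(r), int(c)))
            kept.append(
                PeakCandidate(int(r), int(c), float(v), float(local_mean[r, c]))
            )
            if max_candidates is not None and len(kept) >= max_candidates:
                break
    return kept


def init_snake(
    center: tuple[float, float],
    radius_px: float,
    n_vertices: int = 32,
    image_shape: tuple[int, int] | None = None,
) -> Snake:
    """Circle of ``n_vertices`` equally spaced points around ``center``,
    placed larger than the mark it will contract onto."""
    if radius_px < 2:
        raise ValueError("radius_px must be >= 2")
    if image_shape is not None:
        h, w = image_shape
        if not (0 <= center[0] < h and 0 <= center[1] < w):
            raise ValueError("snake center outside image")
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    verts = np.stack(
        [center[0] + radius_px * np.cos(theta), center[1] + radius_px * np.sin(theta)],
        axis=1,
    )
    return Snake(verts, converged=False)


def _bilinear(img: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Bilinear sample of ``img`` at real-valued (row, col) points, clamped
    to the image border."""
    h, w = img.shape
    r = np.clip(pts[..., 0], 0, h - 1)
    c = np.clip(pts[..., 1], 0, w - 1)
    r0 = np.clip(np.floor(r).astype(int), 0, h - 2) if h > 1 else np.zeros_like(r, int)
    c0 = np.clip(np.floor(c).astype(int), 0, w - 2) if w > 1 else np.zeros_like(c, int)
    dr = r - r0
    dc = c - c0
    return (
        img[r0, c0] * (1 - dr) * (1 - dc)
        + img[r0 + 1, c0] * dr * (1 - dc)
        + img[r0, c0 + 1] * (1 - dr) * dc
        + img[r0 + 1, c0 + 1] * dr * dc
    )


def _stretching(verts: np.ndarray) -> float:
    return float(np.linalg.norm(np.roll(verts, -1, axis=0) - verts, axis=1).sum())


def _bending(verts: np.ndarray) -> float:
    second = np.roll(verts, -1, axis=0) - 2 * verts + np.roll(verts, 1, axis=0)
    return float(np.linalg.norm(second, axis=1).sum())


def snake_energy(
    s: Snake,
    grad_mag: MonoImage | np.ndarray,
    alpha: float = 1.0,
    beta: float = 0.5,
    gamma: float = 2.0,
) -> float:
    """Total snake energy: α·stretching + β·bending − γ·Σ grad(vᵢ).

    Vertices outside the image are clamped to the border for gradient
    sampling (with a logged warning).
    """
    g = grad_mag.pixels if isinstance(grad_mag, MonoImage) else np.asarray(grad_mag)
    h, w = g.shape
    v = s.vertices
    if (v[:, 0].min() < 0 or v[:, 0].max() > h - 1
            or v[:, 1].min() < 0 or v[:, 1].max() > w - 1):
        logger.warning("snake vertex outside image: clamped to border")
    ext = _bilinear(g, v).sum()
    return alpha * _stretching(v) + beta * _bending(v) - gamma * float(ext)


def _proper_crossing(p: np.ndarray, q: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized strict segment-crossing test of segment (p, q) against
    segments (a[k], b[k]); touching at endpoints does not count."""

    def cross(o, d, pt):
        return (d[..., 0] - o[..., 0]) * (pt[..., 1] - o[..., 1]) - (
            d[..., 1] - o[..., 1]
        ) * (pt[..., 0] - o[..., 0])

    d1 = cross(p, q, a)
    d2 = cross(p, q, b)
    d3 = cross(a, b, p)
    d4 = cross(a, b, q)
    return (d1 * d2 < 0) & (d3 * d4 < 0)


def _move_creates_crossing(verts: np.ndarray, i: int, new_pos: np.ndarray) -> bool:
    n = len(verts)
    trial = verts.copy()
    trial[i] = new_pos
    starts = trial
    ends = np.roll(trial, -1, axis=0)
    # edges incident to vertex i
    for e in ((i - 1) % n, i):
        p, q = starts[e], ends[e]
        others = np.ones(n, bool)
        others[[(e - 1) % n, e, (e + 1) % n]] = False  # skip self + neighbors
        if _proper_crossing(p, q, starts[others], ends[others]).any():
            return True
    return False


def _greedy_pass(
    verts: np.ndarray,
    g: np.ndarray,
    offsets: np.ndarray,
    stay_idx: int,
    a: float,
    b: float,
    c: float,
) -> int:
    """One sequential greedy sweep over the vertices.  Each vertex moves to
    the candidate minimising its local energy contribution (the only terms
    it appears in); ties favor staying, crossing-creating moves are
    rejected.  Returns the number of vertices that moved."""
    h, w = g.shape
    n = len(verts)
    moved = 0
    for i in range(n):
        cand = verts[i] + offsets
        cand[:, 0] = np.clip(cand[:, 0], 0, h - 1)
        cand[:, 1] = np.clip(cand[:, 1], 0, w - 1)
        vm2, vm1 = verts[i - 2], verts[i - 1]
        vp1, vp2 = verts[(i + 1) % n], verts[(i + 2) % n]
        d_prev = np.linalg.norm(cand - vm1, axis=1)
        d_next = np.linalg.norm(vp1 - cand, axis=1)
        b_m1 = np.linalg.norm(cand - 2 * vm1 + vm2, axis=1)
        b_i = np.linalg.norm(vp1 - 2 * cand + vm1, axis=1)
        b_p1 = np.linalg.norm(vp2 - 2 * vp1 + cand, axis=1)
        ext = _bilinear(g, cand)
        e = a * (d_prev + d_next) + b * (b_m1 + b_i + b_p1) - c * ext
        e_stay = e[stay_idx]
        better = np.where(e < e_stay - 1e-12)[0]
        if len(better) == 0:
            continue
        for j in better[np.argsort(e[better], kind="stable")]:
            if not _move_creates_crossing(verts, i, cand[j]):
                verts[i] = cand[j]
                moved += 1
                break
    return moved


def evolve_snake_greedy(
    s: Snake,
    grad_mag: MonoImage | np.ndarray,
    params: SnakeParams | None = None,
) -> Snake:
    """Greedy energy minimisation of a snake.

    Each iteration runs a sequential greedy sweep: every vertex moves to
    the position in its (2·search_radius+1)² neighborhood that lowers its
    local energy contribution (ties favor staying put, self-intersecting
    moves are rejected), so the total energy never increases.  Away from
    any gradient, single-vertex moves cannot shorten a smooth 32-gon — the
    inward sagitta is far below one pixel — so whenever a sweep stalls a
    *uniform shrink* of the whole polygon toward its centroid (by up to
    ``search_radius_px``) is tried and kept only if it lowers the total
    energy.  This realises the characteristic behavior of the contour:
    regular, circular contraction until it locks onto the image-gradient
    ridge, where the shrink no longer pays and the external term pins the
    vertices.  Evolution converges when both the sweep and the shrink make
    no progress, or gives up at ``max_iters`` (``converged=False``, logged).
    """
    params = params or SnakeParams()
    g = grad_mag.pixels if isinstance(grad_mag, MonoImage) else np.asarray(grad_mag)
    h, w = g.shape
    a, b, c = params.alpha, params.beta, params.gamma

    rr = np.arange(-params.search_radius_px, params.search_radius_px + 1)
    offsets = np.stack(np.meshgrid(rr, rr, indexing="ij"), axis=-1).reshape(-1, 2)
    offsets = offsets.astype(np.float64)
    stay_idx = int(np.where((offsets == 0).all(axis=1))[0][0])

    verts = s.vertices.copy()
    verts[:, 0] = np.clip(verts[:, 0], 0, h - 1)
    verts[:, 1] = np.clip(verts[:, 1], 0, w - 1)
    n = len(verts)
    converged = False

    def total_energy(v: np.ndarray) -> float:
        return a * _stretching(v) + b * _bending(v) - c * float(_bilinear(g, v).sum())

    for _ in range(params.max_iters):
        moved = _greedy_pass(verts, g, offsets, stay_idx, a, b, c)
        # regular (circular) contraction trial, kept only if it pays
        shrink_accepted = False
        centroid = verts.mean(axis=0)
        radial = verts - centroid
        mean_r = np.linalg.norm(radial, axis=1).mean()
        if mean_r >= 1e-9:
            scale = max(0.0, 1.0 - params.search_radius_px / mean_r)
            shrunk = centroid + scale * radial
            shrunk[:, 0] = np.clip(shrunk[:, 0], 0, h - 1)
            shrunk[:, 1] = np.clip(shrunk[:, 1], 0, w - 1)
            if total_energy(shrunk) < total_energy(verts) - 1e-12:
                verts = shrunk
                shrink_accepted = True
        if moved / n < params.min_moved_fraction and not shrink_accepted:
            converged = True
            break
    if not converged:
        logger.warning("snake did not converge in %d iterations", params.max_iters)
    out = Snake(verts, converged=converged)
    out.energy = snake_energy(out, g, a, b, c)
    return out


def snake_to_region(
    s: Snake, image_shape: tuple[int, int], seed: PeakCandidate | None = None
) -> SegmentedMark:
    """Rasterize the closed snake polygon to the set of pixels whose centers
    fall inside it; an empty raster flags the mark degenerate."""
    rr, cc = draw_polygon(s.vertices[:, 0], s.vertices[:, 1], shape=image_shape)
    region = np.stack([rr, cc], axis=1)
    if len(region) < 1:
        center = tuple(s.vertices.mean(axis=0))
        return SegmentedMark(region, s, center, seed, degenerate=True)
    centroid = (float(rr.mean()), float(cc.mean()))
    return SegmentedMark(region, s, centroid, seed, degenerate=False)


#: Sobel magnitude across an ideal unit step edge — the fixed gradient
#: normalisation scale, so a ratio step of 1.0 maps to gradient strength 1.0
#: regardless of what else is in the image.
SOBEL_UNIT_STEP = 4.0


def sobel_magnitude(ratio: RatioImage, normalize: bool = True) -> MonoImage:
    """Sobel gradient-magnitude image of the ratio image.

    With ``normalize`` the magnitude is divided by the response of a unit
    ratio step, giving the γ energy weight a fixed, image-independent
    meaning: sensor noise stays near zero instead of being inflated to
    full scale on low-contrast (e.g. mark-free) bolls.
    """
    gr = ndimage.sobel(ratio.pixels, axis=0)
    gc = ndimage.sobel(ratio.pixels, axis=1)
    mag = np.hypot(gr, gc)
    if normalize:
        mag = mag / SOBEL_UNIT_STEP
    return MonoImage(mag, ratio.resolution_px_per_mm)


def estimate_init_radius(
    detection_img: np.ndarray,
    peak: PeakCandidate,
    factor: float = 1.5,
    cap_px: float = 40.0,
    min_px: float = 4.0,
) -> tuple[tuple[float, float], float]:
    """Initial snake placement for a peak: a circle larger than the mark,
    whose exact placement is uncritical.

    The center is the centroid of the half-prominence blob under the peak
    (robust when the peak sits off-center, e.g. on a donut ring).  The mark
    extent is the largest radius at which the azimuthal-mean radial
    profile around that center still exceeds the local neighborhood mean
    plus a quarter of the peak prominence — taking the *last* crossing
    skips the attenuated core of donut-shaped marks, and the scan stops
    once the profile has stayed below the level for a few radii so a
    neighboring mark cannot inflate the estimate.  The blob's equivalent
    radius serves as a floor.  The snake starts at ``factor`` times that
    radius, clipped to [min_px, cap_px].
    """
    h, w = detection_img.shape
    half = int(np.ceil(cap_px)) + 2
    r0, r1 = max(peak.row - half, 0), min(peak.row + half + 1, h)
    c0, c1 = max(peak.col - half, 0), min(peak.col + half + 1, w)
    window = detection_img[r0:r1, c0:c1]
    thresh = 0.5 * (peak.value + peak.local_mean)
    labels, _ = ndimage.label(window >= thresh)
    lab = labels[peak.row - r0, peak.col - c0]
    if lab == 0:
        return (float(peak.row), float(peak.col)), min_px
    rows, cols = np.nonzero(labels == lab)
    center = (float(rows.mean()) + r0, float(cols.mean()) + c0)

    blob_r = np.sqrt(len(rows) / np.pi)
    drop_level = peak.local_mean + 0.25 * (peak.value - peak.local_mean)
    theta = np.linspace(0.0, 2.0 * np.pi, 32, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)
    mark_r = 0.0
    below = 0
    for r in range(1, int(np.ceil(cap_px / factor)) + 1):
        pts = np.stack([center[0] + r * ct, center[1] + r * st], axis=1)
        if _bilinear(detection_img, pts).mean() >= drop_level:
            mark_r = r
            below = 0
        else:
            below += 1
            if below >= 4:
                break
    mark_r = max(mark_r, blob_r)
    radius = float(np.clip(factor * mark_r, min_px, cap_px))
    return center, radius
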