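"""Ground-truthed synthetic boll scenes and mark feature tables.

No boll photographs ship with the package, so every pipeline stage is
exercised on generated data with the statistical structure of the real
study:

* **Scenes** — a dark backdrop, an elliptical boll whose red (chlorophyll)
  channel dominates, a low green baseline inside the boll, and planted
  fluorescent marks: true-positive punctures rendered as sharp-edged donuts
  with an attenuated core (the pierced center fluoresces weakly),
  false positives as center-bright irregular blobs (sums of offset
  Gaussians), and needle punctures as smaller, more strongly attenuated
  donuts.  Scenes are emitted at raw-camera scale (36 px/mm, 12-bit), so
  after the pipeline's 2×2 binning every printed constant (18 px/mm,
  15-px peak spacing, 28-px minimum area, 4-px inner circle) applies
  unchanged.

* **Feature tables** — (A, I1/I2) pairs drawn per class from log-normal
  distributions whose medians are the study's group medians: area
  0.35 / 0.6 / 0.27 mm² and intensity ratio 0.96 / 1.2 / 0.86 for the
  infested, control (false-positive) and needle classes.

All randomness flows through a single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .images import ColorImage, bin2x2

__all__ = [
    "ClassCalibration",
    "DEFAULT_CALIBRATIONS",
    "MarkSpec",
    "SceneSpec",
    "GroundTruthMark",
    "sample_mark_table",
    "generate_boll_image",
    "random_scene",
]

RAW_RESOLUTION_PX_PER_MM = 36.0  # 18 px/mm after 2×2 binning
TWELVE_BIT_MAX = 4095.0


@dataclass(frozen=True)
class ClassCalibration:
    """Log-normal calibration of one mark class: medians and log-scale
    dispersions of area (mm²) and intensity ratio I1/I2."""

    median_area_mm2: float
    sigma_log_area: float
    median_ratio: float
    sigma_log_ratio: float

    def __post_init__(self) -> None:
        if self.median_area_mm2 <= 0 or self.median_ratio <= 0:
            raise ValueError("medians must be positive")
        if self.sigma_log_area < 0 or self.sigma_log_ratio < 0:
            raise ValueError("dispersions must be nonnegative")


#: Study-condition calibrations: group medians with a wider spread for the
#: false-positive (control) class, whose sizes vary most.
DEFAULT_CALIBRATIONS: dict[str, ClassCalibration] = {
    "infested": ClassCalibration(0.35, 0.25, 0.96, 0.25),
    "control": ClassCalibration(0.60, 0.40, 1.20, 0.40),
    "needle": ClassCalibration(0.27, 0.25, 0.86, 0.25),
}


def sample_mark_table(
    n_per_class: int | dict[str, int],
    calibrations: dict[str, ClassCalibration] | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw (A, I1/I2) pairs per class from the log-normal calibration.

    A log-normal with log-median m and log-sd σ has sample median → m, so
    large draws reproduce the calibrated group medians; σ = 0 collapses
    every draw onto the median exactly.
    """
    calibrations = calibrations or DEFAULT_CALIBRATIONS
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(n_per_class, int):
        n_per_class = {k: n_per_class for k in calibrations}
    frames = []
    for label, n in n_per_class.items():
        if n < 1:
            raise ValueError("n_per_class must be >= 1")
        cal = calibrations[label]
        area = np.exp(
            rng.normal(math.log(cal.median_area_mm2), cal.sigma_log_area, n)
        )
        ratio = np.exp(
            rng.normal(math.log(cal.median_ratio), cal.sigma_log_ratio, n)
        )
        frames.append(
            pd.DataFrame({"label": label, "area_mm2": area, "ratio": ratio})
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class MarkSpec:
    """One planted mark, in raw-image coordinates.

    ``kind``: true_positive | false_positive | needle.  Donut marks add
    ``green_gain`` counts of green inside ``outer_radius_px``, reduced by
    ``core_attenuation`` inside the core (``core_radius_frac`` of the outer
    radius).  False positives are sharp-rimmed disks topped by a dominant
    central Gaussian and ``n_lobes``−1 offset lobes — irregular and
    brightest near the center.
    """

    kind: str
    center: tuple[float, float]
    outer_radius_px: float
    core_attenuation: float = 0.6
    green_gain: float = 1400.0
    core_radius_frac: float = 0.4
    n_lobes: int = 3  # false positives only

    def __post_init__(self) -> None:
        if self.kind not in ("true_positive", "false_positive", "needle"):
            raise ValueError(f"unknown mark kind {self.kind!r}")
        if self.outer_radius_px < 2:
            raise ValueError("outer_radius_px must be >= 2")
        if not 0.0 <= self.core_attenuation <= 1.0:
            raise ValueError("core_attenuation must be in [0, 1]")


@dataclass
class SceneSpec:
    """Full description of a synthetic boll scene (raw-camera scale)."""

    shape: tuple[int, int] = (384, 384)
    boll_center: tuple[float, float] | None = None  # default: image center
    boll_axes: tuple[float, float] | None = None  # default: 42% of each dim
    background_level: float = 30.0
    red_boll_mean: float = 2200.0
    green_baseline_frac: float = 0.55
    noise_sd_frac: float = 0.01
    marks: list[MarkSpec] = field(default_factory=list)
    resolution_px_per_mm: float = RAW_RESOLUTION_PX_PER_MM
    seed: int | None = None
    min_mark_separation_px: float = 30.0  # = 15 px on the binned image

    def __post_init__(self) -> None:
        if self.boll_center is None:
            self.boll_center = (self.shape[0] / 2.0, self.shape[1] / 2.0)
        if self.boll_axes is None:
            self.boll_axes = (0.42 * self.shape[0], 0.42 * self.shape[1])
        self._validate_marks()

    def _validate_marks(self) -> None:
        cr, cc = self.boll_center
        ar, ac = self.boll_axes
        for m in self.marks:
            u = (m.center[0] - cr) / ar
            v = (m.center[1] - cc) / ac
            if u * u + v * v > 1.0:
                raise ValueError(f"mark at {m.center} outside the boll ellipse")
        for i, a in enumerate(self.marks):
            for b in self.marks[i + 1 :]:
                d = math.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if d < self.min_mark_separation_px:
                    raise ValueError(
                        f"marks {a.center} and {b.center} closer than "
                        f"{self.min_mark_separation_px} px"
                    )


@dataclass
class GroundTruthMark:
    """Planted truth for one mark: class, raw/binned centers, planted area
    and the I1/I2 the noiseless scene would yield."""

    kind: str
    center_raw: tuple[float, float]
    center_binned: tuple[float, float]
    area_mm2: float
    planted_ratio: float


def _render_green_marks(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.shape
    add = np.zeros((h, w))
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    for m in spec.marks:
        d2 = (rows - m.center[0]) ** 2 + (cols - m.center[1]) ** 2
        if m.kind in ("true_positive", "needle"):
            core_r = m.core_radius_frac * m.outer_radius_px
            donut = np.where(
                d2 <= m.outer_radius_px**2,
                np.where(d2 <= core_r**2, 1.0 - m.core_attenuation, 1.0),
                0.0,
            )
            add += m.green_gain * donut
        else:
            # center-bright blob with a defined rim: filled disk plus a
            # dominant central Gaussian and a few offset lobes
            sigma = 0.35 * m.outer_radius_px
            blob = np.where(d2 <= m.outer_radius_px**2, 0.55 * m.green_gain, 0.0)
            blob = blob + 0.8 * m.green_gain * np.exp(-d2 / (2 * sigma**2))
            for _ in range(max(m.n_lobes - 1, 0)):
                off = rng.uniform(-0.4, 0.4, 2) * m.outer_radius_px
                dd2 = (rows - m.center[0] - off[0]) ** 2 + (
                    cols - m.center[1] - off[1]
                ) ** 2
                blob += (
                    m.green_gain
                    * rng.uniform(0.2, 0.4)
                    * np.exp(-dd2 / (2 * (0.7 * sigma) ** 2))
                )
            add += blob
    return add


def _planted_truth(
    spec: SceneSpec,
    red: np.ndarray,
    green: np.ndarray,
    inner_radius_binned_px: float = 4.0,
) -> list[GroundTruthMark]:
    """Ground-truth I1/I2 from the *noiseless* scene, measured on the binned
    ratio with the same equal-area-circle definition as the pipeline."""
    from .metrics import intensity_ratio
    from .images import BollMask, RatioImage

    noiseless = np.stack([red, green, np.zeros_like(red)], axis=-1)
    binned = bin2x2(
        ColorImage(
            np.clip(noiseless, 0, TWELVE_BIT_MAX),
            resolution_px_per_mm=spec.resolution_px_per_mm,
        )
    )
    r = binned.pixels[:, :, 0]
    g = binned.pixels[:, :, 1]
    mask = BollMask((r > 2 * spec.background_level).astype(np.uint8))
    ratio = RatioImage(
        mask.pixels * g / np.maximum(r, 1.0), mask, binned.resolution_px_per_mm
    )
    res_binned = binned.resolution_px_per_mm
    truths = []
    for m in spec.marks:
        cb = (m.center[0] / 2.0 - 0.25, m.center[1] / 2.0 - 0.25)
        r_binned = m.outer_radius_px / 2.0
        area_px_binned = math.pi * r_binned**2
        area = area_px_binned / res_binned**2
        _, _, planted = intensity_ratio(
            cb, int(round(area_px_binned)), ratio, inner_radius_binned_px
        )
        truths.append(
            GroundTruthMark(m.kind, m.center, cb, area, float(planted))
        )
    return truths


def generate_boll_image(spec: SceneSpec) -> tuple[ColorImage, list[GroundTruthMark]]:
    """Render a scene to a raw-scale 12-bit color image plus ground truth.

    The mark geometry is fixed by the scene description; only the additive Gaussian
    channel noise (sd = ``noise_sd_frac`` of the boll's red intensity) and
    the false-positive lobe layout vary with the seed.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    cr, cc = spec.boll_center
    ar, ac = spec.boll_axes
    boll = ((rows - cr) / ar) ** 2 + ((cols - cc) / ac) ** 2 <= 1.0

    red = np.where(boll, spec.red_boll_mean, spec.background_level)
    green = np.where(
        boll,
        spec.green_baseline_frac * spec.red_boll_mean,
        spec.background_level,
    )
    green = green + _render_green_marks(spec, rng)

    truths = _planted_truth(spec, red.copy(), green.copy())

    sd = spec.noise_sd_frac * spec.red_boll_mean
    red = red + rng.normal(0.0, sd, (h, w))
    green = green + rng.normal(0.0, sd, (h, w))
    pixels = np.stack([red, green, np.full((h, w), spec.background_level)], axis=-1)
    pixels = np.clip(pixels, 0.0, TWELVE_BIT_MAX)
    img = ColorImage(pixels, bit_depth=12, resolution_px_per_mm=spec.resolution_px_per_mm)
    return img, truths


def random_scene(
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    n_true_positive: int = 3,
    n_false_positive: int = 1,
    n_needle: int = 0,
    shape: tuple[int, int] = (384, 384),
    calibrations: dict[str, ClassCalibration] | None = None,
) -> SceneSpec:
    """Draw a SceneSpec with mark sizes sampled from the class calibrations
    and rejection-sampled non-overlapping placements inside the boll."""
    calibrations = calibrations or DEFAULT_CALIBRATIONS
    if rng is None:
        rng = np.random.default_rng(seed)
    spec = SceneSpec(shape=shape, seed=int(rng.integers(2**31)))
    cr, cc = spec.boll_center
    ar, ac = spec.boll_axes

    kinds = (
        ["true_positive"] * n_true_positive
        + ["false_positive"] * n_false_positive
        + ["needle"] * n_needle
    )
    label_of = {
        "true_positive": "infested",
        "false_positive": "control",
        "needle": "needle",
    }
    res_binned = spec.resolution_px_per_mm / 2.0
    marks: list[MarkSpec] = []
    for kind in kinds:
        cal = calibrations[label_of[kind]]
        area = float(
            np.exp(rng.normal(math.log(cal.median_area_mm2), cal.sigma_log_area))
        )
        # raw-scale outer radius from the planted binned-scale area
        r_raw = 2.0 * math.sqrt(area * res_binned**2 / math.pi)
        r_raw = float(np.clip(r_raw, 8.0, 30.0))
        for _ in range(500):
            u, v = rng.uniform(-0.75, 0.75, 2)
            if u * u + v * v > 0.70**2:  # keep the whole mark well inside
                continue
            center = (cr + u * ar, cc + v * ac)
            ok = all(
                math.hypot(center[0] - m.center[0], center[1] - m.center[1])
                >= spec.min_mark_separation_px + r_raw
                for m in marks
            )
            if ok:
                break
        else:  # pragma: no cover - pathological packing
            raise RuntimeError("could not place mark without overlap")
        if kind == "false_positive":
            marks.append(
                MarkSpec(kind, center, r_raw, green_gain=float(rng.uniform(1100, 1700)),
                         n_lobes=int(rng.integers(2, 5)))
            )
        else:
            att = (
                float(rng.uniform(0.5, 0.7))
                if kind == "true_positive"
                else float(rng.uniform(0.75, 0.85))
            )
            marks.append(
                MarkSpec(kind, center, r_raw, core_attenuation=att,
                         green_gain=float(rng.uniform(1100, 1700)))
            )
    return replace(spec, marks=marks)
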