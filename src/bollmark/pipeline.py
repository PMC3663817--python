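"""End-to-end orchestration: image → ratio image → candidate peaks →
snakes → marks → filters → rectangle verdicts, aggregated into a report."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import RectangleCriterion, classify_table
from .detect import (
    SnakeParams,
    estimate_init_radius,
    evolve_snake_greedy,
    find_local_maxima,
    init_snake,
    ratio_to_counts,
    snake_to_region,
    sobel_magnitude,
)
from .images import ColorImage, ImagingConfig, process_color_image
from .metrics import MARK_COLUMNS, FilterConfig, apply_filters, measure_mark

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionConfig",
    "PipelineConfig",
    "RunReport",
    "process_image",
    "run_pipeline",
]


@dataclass
class DetectionConfig:
    """Candidate detection and snake-initialisation settings.

    ``min_difference`` is in 12-bit counts on the rescaled ratio image.
    ``max_candidates`` bounds the number of seeds per image (strongest
    first) so that sensor-noise maxima cannot flood the segmentation stage.
    """

    min_distance_px: int = 15
    min_difference: float = 10.0
    neighborhood_radius_px: int = 15
    max_candidates: int = 50
    init_radius_factor: float = 1.5
    init_radius_cap_px: float = 40.0
    snake: SnakeParams = field(default_factory=SnakeParams)


@dataclass
class PipelineConfig:
    """All module configs plus the run seed."""

    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    criterion: RectangleCriterion = field(default_factory=RectangleCriterion)
    min_positive_marks_per_boll: int = 1
    seed: int = 0

    def hash(self) -> str:
        """Stable hash of the full configuration; changing any threshold
        changes it."""
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _build(cls, data: dict):
    """Recursively build a (nested) config dataclass, rejecting unknown
    keys."""
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        sub = _DATACLASS_FIELDS.get((cls, name))
        if sub is not None and isinstance(value, dict):
            kwargs[name] = _build(sub, value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_DATACLASS_FIELDS = {
    (PipelineConfig, "imaging"): ImagingConfig,
    (PipelineConfig, "detection"): DetectionConfig,
    (PipelineConfig, "filters"): FilterConfig,
    (PipelineConfig, "criterion"): RectangleCriterion,
    (DetectionConfig, "snake"): SnakeParams,
}


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline config, rejecting unknown keys at every level."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _build(PipelineConfig, data)


def process_image(
    img: ColorImage,
    cfg: PipelineConfig | None = None,
    image_id: str = "image",
    label: str = "unknown",
) -> tuple[pd.DataFrame, dict]:
    """Run the full chain on one color image.

    Returns the per-mark feature table (kept and rejected marks, with
    verdicts) and a details dict holding the ratio image, snakes and peaks
    for debugging/overlays.
    """
    cfg = cfg or PipelineConfig()
    ratio = process_color_image(img, cfg.imaging)
    details: dict = {"ratio": ratio, "snakes": [], "peaks": [], "marks": []}
    if not ratio.mask.pixels.any():
        logger.error("%s: no boll detected", image_id)
        details["no_boll"] = True
        return pd.DataFrame(columns=MARK_COLUMNS), details

    det = cfg.detection
    peaks = find_local_maxima(
        ratio,
        min_distance_px=det.min_distance_px,
        min_difference=det.min_difference,
        neighborhood_radius_px=det.neighborhood_radius_px,
        max_candidates=det.max_candidates,
    )
    details["peaks"] = peaks

    detection_img = ratio_to_counts(ratio.pixels)
    grad = sobel_magnitude(ratio)

    marks = []
    for pk in peaks:
        center, r0 = estimate_init_radius(
            detection_img, pk, det.init_radius_factor, det.init_radius_cap_px
        )
        snake = init_snake(center, r0, image_shape=ratio.pixels.shape)
        snake = evolve_snake_greedy(snake, grad, det.snake)
        seg = snake_to_region(snake, ratio.pixels.shape, seed=pk)
        details["snakes"].append(snake)
        marks.append(measure_mark(seg, ratio, cfg.filters, label=label))
    kept, rejected = apply_filters(marks, cfg.filters)
    details["marks"] = marks

    rows = []
    for i, m in enumerate(marks):
        rows.append(
            {
                "image_id": image_id,
                "mark_id": i,
                "label": m.label,
                "area_px": m.area_px,
                "area_mm2": m.area_mm2,
                "integrated_intensity": m.integrated_intensity,
                "aspect_ratio": m.aspect_ratio,
                "convexity": m.convexity,
                "I1": m.I1,
                "I2": m.I2,
                "ratio": m.ratio,
                "kept": m.kept,
                "reject_reason": m.reject_reason,
            }
        )
    table = pd.DataFrame(rows, columns=MARK_COLUMNS)
    if len(table):
        valid = table["kept"] & np.isfinite(table["ratio"])
        table["positive"] = False
        table.loc[valid, "positive"] = classify_table(
            table.loc[valid], cfg.criterion
        )
    else:
        table["positive"] = pd.Series(dtype=bool)
    return table, details


@dataclass
class RunReport:
    """Aggregated result of a pipeline run."""

    marks: pd.DataFrame
    per_image: dict[str, dict]
    config_hash: str
    version: str
    timestamp: str
    boll_infested: bool | None = None

    def to_json_dict(self) -> dict:
        return {
            "version": self.version,
            "config_hash": self.config_hash,
            "timestamp": self.timestamp,
            "n_marks": int(len(self.marks)),
            "n_kept": int(self.marks["kept"].sum()) if len(self.marks) else 0,
            "n_positive": int(self.marks["positive"].sum()) if len(self.marks) else 0,
            "boll_infested": self.boll_infested,
            "per_image": self.per_image,
        }


def run_pipeline(
    images: list[tuple[str, ColorImage]],
    cfg: PipelineConfig | None = None,
    labels: dict[str, str] | None = None,
) -> RunReport:
    """Process a list of (image_id, image) pairs — e.g. the four rotation
    views of one boll — and aggregate mark tables.

    The boll is flagged infested when at least
    ``min_positive_marks_per_boll`` marks across all views classify
    positive.  Unreadable/failed images are skipped with a logged error.
    """
    cfg = cfg or PipelineConfig()
    labels = labels or {}
    tables = []
    per_image: dict[str, dict] = {}
    for image_id, img in images:
        try:
            table, details = process_image(
                img, cfg, image_id=image_id, label=labels.get(image_id, "unknown")
            )
        except Exception:  # noqa: BLE001 - keep the batch running
            logger.exception("failed to process %s; skipping", image_id)
            per_image[image_id] = {"status": "error"}
            continue
        status = "no boll detected" if details.get("no_boll") else "ok"
        per_image[image_id] = {
            "status": status,
            "n_marks": int(len(table)),
            "n_positive": int(table["positive"].sum()) if len(table) else 0,
        }
        tables.append(table)
    marks = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(columns=MARK_COLUMNS + ["positive"])
    )
    n_pos = int(marks["positive"].sum()) if len(marks) else 0
    return RunReport(
        marks=marks,
        per_image=per_image,
        config_hash=cfg.hash(),
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
        boll_infested=n_pos >= cfg.min_positive_marks_per_boll,
    )
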