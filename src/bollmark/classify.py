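"""Two-threshold rectangle classification of marks and ROC analysis.

In the (A, I1/I2) feature plane, puncture marks concentrate in the lower
left corner: small area and a donut profile.  The rectangle criterion
declares a mark positive when A < a_max and I1/I2 < r_max (defaults
0.6 mm² and 1.2, strict inequalities).  Sweeping the rectangle corner along
the diagonal through the origin trades sensitivity against specificity and
yields the ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "RectangleCriterion",
    "ContingencyTable",
    "DEFAULT_ROC_CORNERS",
    "classify",
    "classify_table",
    "contingency",
    "roc_sweep",
]

#: Rectangle corner points (a_max in mm², r_max) swept for the ROC curve,
#: from the largest rectangle (high sensitivity) to the smallest.
DEFAULT_ROC_CORNERS: list[tuple[float, float]] = [
    (1.5, 1.4),
    (1.0, 1.2),
    (0.8, 1.1),
    (0.65, 1.05),
    (0.5, 1.0),
    (0.4, 0.98),
]


@dataclass(frozen=True)
class RectangleCriterion:
    """Joint threshold A < a_max (mm²) and I1/I2 < r_max."""

    a_max: float = 0.6
    r_max: float = 1.2

    def __post_init__(self) -> None:
        if self.a_max <= 0 or self.r_max <= 0:
            raise ValueError("rectangle thresholds must be positive")


def classify(
    area_mm2: float, ratio: float, c: RectangleCriterion | None = None
) -> bool:
    """True iff the mark falls strictly inside the rectangle."""
    c = c or RectangleCriterion()
    return bool(area_mm2 < c.a_max and ratio < c.r_max)


def classify_table(
    marks: pd.DataFrame, c: RectangleCriterion | None = None
) -> pd.Series:
    """Vectorized rectangle verdict for a mark table with ``area_mm2`` and
    ``ratio`` columns."""
    c = c or RectangleCriterion()
    return (marks["area_mm2"] < c.a_max) & (marks["ratio"] < c.r_max)


@dataclass
class ContingencyTable:
    """Counts and percentages of marks passing/failing the area rule, the
    ratio rule and the combined rule, per label group.

    ``pooled_percent`` uses the pooled total of both groups as denominator
    (so all cells of a criterion pair sum to 100 across groups);
    ``group_percent`` uses each group's own size.
    """

    counts: pd.DataFrame
    pooled_percent: pd.DataFrame
    group_percent: pd.DataFrame
    total: int

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "counts": self.counts.to_dict(),
            "pooled_percent": self.pooled_percent.round(1).to_dict(),
            "group_percent": self.group_percent.round(1).to_dict(),
        }


_CELLS = [
    "A_pass",
    "A_fail",
    "ratio_pass",
    "ratio_fail",
    "combined_pass",
    "combined_fail",
]


def contingency(
    marks: pd.DataFrame,
    c: RectangleCriterion | None = None,
    groups: tuple[str, str] = ("infested", "control"),
) -> ContingencyTable:
    """Contingency table of the single and combined criteria for two labeled
    groups; percentages are reported with the pooled denominator."""
    c = c or RectangleCriterion()
    sub = marks[marks["label"].isin(groups)]
    for g in groups:
        if (sub["label"] == g).sum() == 0:
            raise ValueError(f"empty group: {g}")
    total = len(sub)
    rows = {}
    for g in groups:
        df = sub[sub["label"] == g]
        a = df["area_mm2"] < c.a_max
        r = df["ratio"] < c.r_max
        both = a & r
        rows[g] = [
            int(a.sum()),
            int((~a).sum()),
            int(r.sum()),
            int((~r).sum()),
            int(both.sum()),
            int((~both).sum()),
        ]
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=_CELLS)
    pooled = counts / total * 100.0
    group = counts.div(counts["A_pass"] + counts["A_fail"], axis=0) * 100.0
    return ContingencyTable(counts, pooled, group, total)


def roc_sweep(
    marks: pd.DataFrame,
    corner_points: list[tuple[float, float]] | None = None,
    positive_label: str = "infested",
    negative_label: str = "control",
) -> pd.DataFrame:
    """Sensitivity/specificity along a sweep of rectangle corners.

    Sensitivity is the fraction of ``positive_label`` marks classified
    positive; specificity the fraction of ``negative_label`` marks
    classified negative (1 − false-positive rate).
    """
    corners = corner_points if corner_points is not None else DEFAULT_ROC_CORNERS
    pos = marks[marks["label"] == positive_label]
    neg = marks[marks["label"] == negative_label]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both label groups must be non-empty")
    rows = []
    for a_max, r_max in corners:
        crit = RectangleCriterion(a_max, r_max)
        sens = float(classify_table(pos, crit).mean())
        spec = float((~classify_table(neg, crit)).mean())
        rows.append(
            {
                "a_max": a_max,
                "r_max": r_max,
                "sensitivity": sens,
                "specificity": spec,
            }
        )
    return pd.DataFrame(rows)
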