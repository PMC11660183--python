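"""Per-class and aggregate multi-label performance metrics with banded cutoffs.

Precision, recall and F1 are computed per class from pooled true/false
positive and false negative counts; macro-F1 is the arithmetic mean of the
ten per-class F1 scores and micro-F1 pools the counts across classes,
``sum(TP) / (sum(TP) + 0.5*(sum(FP) + sum(FN)))``. Metric values are mapped
onto the six published sensitivity bands used in food-environment
classification work (very poor < 0.20 up to excellent >= 0.90).

Degenerate 0/0 ratios (a class with no predicted or no actual positives) are
defined as 0 with a logged warning.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence

import pandas as pd

from .classes import FoodClass, LabelSet

__all__ = [
    "Band",
    "ClassCounts",
    "MetricsReport",
    "band",
    "confusion_counts",
    "f1_from_pr",
    "summarize",
]

logger = logging.getLogger(__name__)


class Band(enum.IntEnum):
    """Published sensitivity cutoff bands, totally ordered."""

    VERY_POOR = 0
    POOR = 1
    FAIR = 2
    MODERATE = 3
    GOOD = 4
    EXCELLENT = 5

    def __str__(self) -> str:  # 'good', 'excellent', ...
        return self.name.lower()


# Half-open band edges; the printed cutoffs have gaps ("<20", "21-30", ...)
# which are resolved as contiguous intervals so every value in [0,1] lands in
# exactly one band.
_BAND_EDGES = [
    (0.20, Band.VERY_POOR),
    (0.30, Band.POOR),
    (0.50, Band.FAIR),
    (0.71, Band.MODERATE),
    (0.90, Band.GOOD),
]


def band(metric: float) -> Band:
    """Map a metric in [0, 1] onto its sensitivity band.

    Intervals are half-open: [0,.20) very poor, [.20,.30) poor, [.30,.50)
    fair, [.50,.71) moderate, [.71,.90) good, [.90,1] excellent.
    """
    if not 0.0 <= metric <= 1.0:
        raise ValueError(f"metric must be in [0, 1], got {metric}")
    for upper, b in _BAND_EDGES:
        if metric < upper:
            return b
    return Band.EXCELLENT


@dataclass
class ClassCounts:
    """Pooled confusion counts (TP, FP, FN) per food class."""

    tp: Dict[FoodClass, int] = field(default_factory=dict)
    fp: Dict[FoodClass, int] = field(default_factory=dict)
    fn: Dict[FoodClass, int] = field(default_factory=dict)
    n_examples: int = 0

    def __post_init__(self):
        for c in FoodClass:
            for d in (self.tp, self.fp, self.fn):
                d.setdefault(c, 0)
                if d[c] < 0:
                    raise ValueError(f"negative count for {c.value}")


def confusion_counts(
    predicted: Sequence[LabelSet], actual: Sequence[LabelSet]
) -> ClassCounts:
    """Tally per-class TP/FP/FN over aligned predicted/actual label sets."""
    if len(predicted) != len(actual):
        raise ValueError(
            f"predicted ({len(predicted)}) and actual ({len(actual)}) "
            "lists differ in length"
        )
    counts = ClassCounts(n_examples=len(predicted))
    for pred, act in zip(predicted, actual):
        for c in FoodClass:
            p, a = c in pred, c in act
            if p and a:
                counts.tp[c] += 1
            elif p and not a:
                counts.fp[c] += 1
            elif a and not p:
                counts.fn[c] += 1
    return counts


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must be in [0, 1]")
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def _safe_ratio(num: int, den: int, what: str, cls: FoodClass) -> float:
    if den == 0:
        logger.warning("%s undefined (0/0) for %s; defined as 0", what, cls.value)
        return 0.0
    return num / den


@dataclass
class MetricsReport:
    """Per-class precision/recall/F1 with bands, plus micro and macro F1."""

    precision: Dict[FoodClass, float]
    recall: Dict[FoodClass, float]
    f1: Dict[FoodClass, float]
    precision_band: Dict[FoodClass, Band]
    recall_band: Dict[FoodClass, Band]
    micro_f1: float
    macro_f1: float
    n_examples: int

    def to_frame(self) -> pd.DataFrame:
        """Tabular layout: one row per class (precision, recall, F1, bands)."""
        rows = [
            {
                "class": c.display_name,
                "precision": self.precision[c],
                "recall": self.recall[c],
                "f1": self.f1[c],
                "precision_band": str(self.precision_band[c]),
                "recall_band": str(self.recall_band[c]),
            }
            for c in FoodClass
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "per_class": {
                c.value: {
                    "precision": self.precision[c],
                    "recall": self.recall[c],
                    "f1": self.f1[c],
                    "precision_band": str(self.precision_band[c]),
                    "recall_band": str(self.recall_band[c]),
                }
                for c in FoodClass
            },
            "micro_f1": self.micro_f1,
            "macro_f1": self.macro_f1,
            "n_examples": self.n_examples,
        }

    def save_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def summarize(counts: ClassCounts) -> MetricsReport:
    """Turn pooled confusion counts into a full metrics report."""
    precision: Dict[FoodClass, float] = {}
    recall: Dict[FoodClass, float] = {}
    f1: Dict[FoodClass, float] = {}
    for c in FoodClass:
        tp, fp, fn = counts.tp[c], counts.fp[c], counts.fn[c]
        precision[c] = _safe_ratio(tp, tp + fp, "precision", c)
        recall[c] = _safe_ratio(tp, tp + fn, "recall", c)
        f1[c] = f1_from_pr(precision[c], recall[c])
    macro = sum(f1.values()) / len(f1)
    tot_tp = sum(counts.tp.values())
    tot_fp = sum(counts.fp.values())
    tot_fn = sum(counts.fn.values())
    denom = tot_tp + 0.5 * (tot_fp + tot_fn)
    micro = tot_tp / denom if denom > 0 else 0.0
    return MetricsReport(
        precision=precision,
        recall=recall,
        f1=f1,
        precision_band={c: band(precision[c]) for c in FoodClass},
        recall_band={c: band(recall[c]) for c in FoodClass},
        micro_f1=micro,
        macro_f1=macro,
        n_examples=counts.n_examples,
    )
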