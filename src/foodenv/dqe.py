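"""Data-quality enhancement: audit an external tag taxonomy with model labels.

Restaurant inspection extracts carry their own service-description and venue
tags, collected independently of the classifier. Cross-tabulating classifier
labels against those tags surfaces taxonomy problems: a high-count cell where
the model's class contradicts the tag (say, names labeled Fast Food under a
'Fine Dining' tag) is a candidate for manual review, and records with vague
venue tags ('Other') can be bucketed by what the model inferred. The module
reports; it never rewrites source tags — the analyst decides.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Set, Tuple

import pandas as pd

from .classes import FoodClass, LabelSet
from .records import StoreRecord

__all__ = [
    "AgreementTable",
    "OtherBreakdown",
    "agreement_table",
    "impute_other",
    "discrepancy_report",
    "MISSING_TAG",
]

#: Reserved column for records lacking the tag field.
MISSING_TAG = "(missing)"

_DEFAULT_RESTRICT = frozenset({FoodClass.FAST_FOOD, FoodClass.RESTAURANT})


@dataclass
class AgreementTable:
    """Counts of (restricted classifier class, observed tag value) pairs.

    A record holding several restricted classes contributes once per held
    class, so cell counts sum to the number of restricted records times their
    restricted-label multiplicity. Records whose labels miss the restriction
    entirely are excluded and counted in ``excluded_count`` (this is how e.g.
    stores labeled only Sweets/Desserts or Juice/Coffee are kept out of a
    Fast Food vs Restaurant audit).
    """

    rows: Tuple[FoodClass, ...]
    columns: Tuple[str, ...]
    counts: Dict[Tuple[FoodClass, str], int] = field(default_factory=dict)
    excluded_count: int = 0
    tag_field: str = "service_description"

    def count(self, cls: FoodClass, tag: str) -> int:
        return self.counts.get((cls, tag), 0)

    def to_frame(self) -> pd.DataFrame:
        data = {
            tag: [self.count(cls, tag) for cls in self.rows] for tag in self.columns
        }
        return pd.DataFrame(data, index=[c.display_name for c in self.rows])

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    def to_dict(self) -> dict:
        return {
            "tag_field": self.tag_field,
            "rows": [c.value for c in self.rows],
            "columns": list(self.columns),
            "counts": {
                f"{cls.value}|{tag}": n for (cls, tag), n in sorted(
                    self.counts.items(), key=lambda kv: (kv[0][0].index, kv[0][1])
                )
            },
            "excluded_count": self.excluded_count,
        }

    def save_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def agreement_table(
    records: Sequence[Tuple[StoreRecord, LabelSet]],
    tag_field: str = "service_description",
    restrict_to: Set[FoodClass] = _DEFAULT_RESTRICT,
) -> AgreementTable:
    """Cross-tabulate classifier labels against an external tag field.

    Keeps records whose label set intersects ``restrict_to`` and counts one
    cell per (held restricted class, observed tag value); records lacking the
    tag are tallied under the reserved ``MISSING_TAG`` column.
    """
    if tag_field not in ("service_description", "venue_tag"):
        raise ValueError(
            f"tag_field must be 'service_description' or 'venue_tag', got {tag_field!r}"
        )
    if not restrict_to:
        raise ValueError("restrict_to must be non-empty")
    rows = tuple(sorted(restrict_to, key=lambda c: c.index))
    counts: Dict[Tuple[FoodClass, str], int] = {}
    columns: List[str] = []
    excluded = 0
    for rec, labels in records:
        held = frozenset(labels) & restrict_to
        if not held:
            excluded += 1
            continue
        tag = getattr(rec, tag_field) or MISSING_TAG
        if tag not in columns:
            columns.append(tag)
        for cls in held:
            counts[(cls, tag)] = counts.get((cls, tag), 0) + 1
    return AgreementTable(
        rows=rows,
        columns=tuple(sorted(columns)),
        counts=counts,
        excluded_count=excluded,
        tag_field=tag_field,
    )


@dataclass(frozen=True)
class OtherBreakdown:
    """How the classifier buckets records with a vague ('Other') venue tag."""

    fraction_restaurant_no_bar: float
    fraction_restaurant_with_bar: float
    fraction_other_classes: float
    fraction_unlabeled: float

    def __post_init__(self):
        total = (
            self.fraction_restaurant_no_bar
            + self.fraction_restaurant_with_bar
            + self.fraction_other_classes
            + self.fraction_unlabeled
        )
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total}")

    def to_dict(self) -> dict:
        return {
            "fraction_restaurant_no_bar": self.fraction_restaurant_no_bar,
            "fraction_restaurant_with_bar": self.fraction_restaurant_with_bar,
            "fraction_other_classes": self.fraction_other_classes,
            "fraction_unlabeled": self.fraction_unlabeled,
        }

    def save_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def impute_other(
    records: Sequence[Tuple[StoreRecord, LabelSet]]
) -> OtherBreakdown:
    """Bucket vague-venue records by the classifier's inference.

    Intended for records whose venue tag is 'Other': the share inferred as a
    restaurant without a bar maps to 'Restaurant (no bar)', with a bar to
    'Restaurant (with Bar)'; the rest carry some other class or no label.
    """
    if not records:
        raise ValueError("impute_other requires at least one record")
    n = len(records)
    no_bar = with_bar = other = unlabeled = 0
    for _, labels in records:
        labels = frozenset(labels)
        is_resto = FoodClass.RESTAURANT in labels or FoodClass.FAST_FOOD in labels
        has_bar = FoodClass.ALCOHOL_BAR in labels
        if is_resto and not has_bar:
            no_bar += 1
        elif is_resto and has_bar:
            with_bar += 1
        elif labels:
            other += 1
        else:
            unlabeled += 1
    return OtherBreakdown(
        fraction_restaurant_no_bar=no_bar / n,
        fraction_restaurant_with_bar=with_bar / n,
        fraction_other_classes=other / n,
        fraction_unlabeled=unlabeled / n,
    )


def discrepancy_report(
    table: AgreementTable,
    alignment: Mapping[str, FoodClass],
) -> List[Tuple[FoodClass, str, int]]:
    """Rank cells where the model's class contradicts the tag's expected class.

    ``alignment`` maps tag values to their expected class (e.g. 'Fine
    Dining' -> Restaurant). Returns (held class, tag, count) for every
    nonzero cell whose class differs from the expectation, sorted by count
    descending (ties by class order then tag). Unaligned tags are skipped.
    """
    out: List[Tuple[FoodClass, str, int]] = []
    for (cls, tag), n in table.counts.items():
        if n == 0 or tag not in alignment:
            continue
        if alignment[tag] != cls:
            out.append((cls, tag, n))
    out.sort(key=lambda item: (-item[2], item[0].index, item[1]))
    return out
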