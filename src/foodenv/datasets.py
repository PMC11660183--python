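"""Leakage-controlled train/validation/test dataset construction.

Store directories contain many observations of the same name (chains,
resurveys). Training on raw rows would leak names across the split, so
examples are built per *normalized name*: observations are deduplicated and
the modal full label set is kept (ties broken by survey recency, then by
record id). High-frequency chain names (more than 10 locations) are set aside
before the split and added back to training only, so the model memorizes them
without inflating held-out performance; the remaining names are shuffled and
partitioned 50/25/25.
"""

from __future__ import annotations

import datetime as dt
import json
import unicodedata
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .classes import LabelSet
from .records import StoreRecord

__all__ = [
    "LabeledExample",
    "DatasetSplit",
    "normalize_name",
    "deduplicate_modal",
    "split_dataset",
]


@dataclass(frozen=True)
class LabeledExample:
    """One training example: a normalized store name with its label set."""

    normalized_name: str
    labels: LabelSet
    provenance: Tuple[str, ...] = ()

    def __post_init__(self):
        if not self.normalized_name:
            raise ValueError("normalized_name must be non-empty")


@dataclass
class DatasetSplit:
    """Train/validation/test partitions plus the memorized chain subset."""

    train: List[LabeledExample]
    validation: List[LabeledExample]
    test: List[LabeledExample]
    memorized: List[LabeledExample] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self):
        names = [
            {e.normalized_name for e in part}
            for part in (self.train, self.validation, self.test)
        ]
        if names[0] & names[1] or names[0] & names[2] or names[1] & names[2]:
            raise ValueError("normalized names leak across split parts")
        mem = {e.normalized_name for e in self.memorized}
        if not mem <= names[0]:
            raise ValueError("memorized examples must be a subset of train")
        if mem & names[1] or mem & names[2]:
            raise ValueError("memorized names must not appear in validation/test")

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "sizes": {
                "train": len(self.train),
                "validation": len(self.validation),
                "test": len(self.test),
                "memorized": len(self.memorized),
            },
            "memorized_names": sorted(e.normalized_name for e in self.memorized),
        }

    def save_manifest(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2)


def normalize_name(name: str) -> str:
    """Normalize a raw store name for deduplication and classification.

    Unicode NFKC normalization, casefolding, and whitespace collapse.
    Punctuation (apostrophes etc.) is retained — store names carry meaningful
    punctuation. Idempotent by construction.
    """
    if name is None or not name.strip():
        raise ValueError("store name is empty or whitespace-only")
    normalized = unicodedata.normalize("NFKC", name).casefold()
    return " ".join(normalized.split())


_EPOCH = dt.date(1, 1, 1)


def deduplicate_modal(
    records: Sequence[Tuple[StoreRecord, LabelSet]]
) -> List[LabeledExample]:
    """Collapse records to one example per normalized name with modal labels.

    The kept label set is the most frequent *full* label combination among
    the name's records. Frequency ties go to the label set of the most
    recently surveyed record; any remaining tie is broken deterministically
    by record_id order (earliest id wins).
    """
    groups: Dict[str, List[Tuple[StoreRecord, LabelSet]]] = defaultdict(list)
    for rec, labels in records:
        groups[normalize_name(rec.name)].append((rec, frozenset(labels)))

    out: List[LabeledExample] = []
    for name in sorted(groups):
        grp = groups[name]
        counts = Counter(labels for _, labels in grp)
        top = max(counts.values())
        tied = {ls for ls, c in counts.items() if c == top}
        if len(tied) == 1:
            chosen = next(iter(tied))
        else:
            # Recency first, then ascending record_id for full determinism.
            candidates = [(rec, ls) for rec, ls in grp if ls in tied]
            candidates.sort(
                key=lambda item: (
                    -(item[0].survey_date or _EPOCH).toordinal(),
                    item[0].record_id,
                )
            )
            chosen = candidates[0][1]
        out.append(
            LabeledExample(
                normalized_name=name,
                labels=chosen,
                provenance=tuple(rec.record_id for rec, _ in grp),
            )
        )
    return out


def split_dataset(
    examples: Sequence[LabeledExample],
    location_counts: Mapping[str, int],
    seed: int,
) -> DatasetSplit:
    """Split examples 50/25/25 with chain names memorized into train.

    ``location_counts`` maps each normalized name to the number of distinct
    locations bearing it before deduplication; names with more than 10
    locations are set aside from the split and appended to training so the
    classifier memorizes them. The remainder is shuffled with ``seed`` and
    partitioned with floor rounding, the remainder going to train.
    """
    missing = [e.normalized_name for e in examples if e.normalized_name not in location_counts]
    if missing:
        raise ValueError(
            f"location_counts missing {len(missing)} names, e.g. {missing[:3]}"
        )
    memorized = [e for e in examples if location_counts[e.normalized_name] > 10]
    rest = [e for e in examples if location_counts[e.normalized_name] <= 10]
    if len(rest) < 4:
        raise ValueError(
            "need at least 4 non-memorized examples to form three non-empty parts"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rest))
    shuffled = [rest[i] for i in order]
    n = len(shuffled)
    n_val = n // 4
    n_test = n // 4
    n_train = n - n_val - n_test
    train = shuffled[:n_train] + memorized
    validation = shuffled[n_train : n_train + n_val]
    test = shuffled[n_train + n_val :]
    return DatasetSplit(
        train=train,
        validation=validation,
        test=test,
        memorized=list(memorized),
        seed=seed,
    )
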