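"""Rule-based conversion of surveyor taxonomy tags into the ten-class labels.

Storefront directories arrive labeled in a vendor taxonomy: a coarse meta
category ('Food', 'Essentials', 'Drink', ...), granular venue tags
('supermarket', 'pizzeria', ...) and service flags ('dine-in',
'quick-bites'). This module declares a small rule language sufficient to
express the published conversion into the ten food-environment classes and
ships a default rule set. Rules only ever *add* labels (their emits are
unioned), so applying a rule set is order-independent and adding a tag to a
record can never remove a label.

A rule matches a record iff all of its non-empty conditions hold:

* ``required_meta`` — the record's meta category is in this set;
* ``any_of_tags`` — the record shares at least one tag with this set;
* ``required_flags`` — every flag in this set is on the record;
* ``disqualify_if_only`` — the record's full tag set is NOT a subset of this
  set (expresses "but not if it only had the tag X").

Tag, flag and meta matching is case-insensitive after whitespace trimming,
since administrative tags vary in casing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import FrozenSet, Iterable, List, Sequence

import yaml

from .classes import FoodClass, LabelSet
from .records import StoreRecord

__all__ = [
    "TaxonomyRule",
    "TaxonomyMap",
    "load_taxonomy",
    "save_taxonomy",
    "map_record",
    "default_taxonomy_path",
    "DEFAULT_META_ALLOWLIST",
]

#: Meta categories considered part of the food environment; records outside
#: this allowlist receive the empty label set.
DEFAULT_META_ALLOWLIST = frozenset({"food", "essentials", "drink"})


def _norm_token(s: str) -> str:
    return s.strip().lower()


def _norm_set(items: Iterable[str]) -> FrozenSet[str]:
    return frozenset(_norm_token(s) for s in items if s and s.strip())


@dataclass(frozen=True)
class TaxonomyRule:
    """One conversion rule; see module docstring for matching semantics."""

    rule_id: str
    emit: FrozenSet[FoodClass]
    required_meta: FrozenSet[str] = frozenset()
    any_of_tags: FrozenSet[str] = frozenset()
    disqualify_if_only: FrozenSet[str] = frozenset()
    required_flags: FrozenSet[str] = frozenset()

    def __post_init__(self):
        if not self.rule_id:
            raise ValueError("rule_id must be non-empty")
        if not self.emit:
            raise ValueError(f"rule {self.rule_id!r}: emit set must be non-empty")
        object.__setattr__(self, "emit", frozenset(self.emit))
        object.__setattr__(self, "required_meta", _norm_set(self.required_meta))
        object.__setattr__(self, "any_of_tags", _norm_set(self.any_of_tags))
        object.__setattr__(
            self, "disqualify_if_only", _norm_set(self.disqualify_if_only)
        )
        object.__setattr__(self, "required_flags", _norm_set(self.required_flags))

    def matches(
        self, meta: str, tags: FrozenSet[str], flags: FrozenSet[str]
    ) -> bool:
        """Evaluate the rule against normalized record fields."""
        if self.required_meta and meta not in self.required_meta:
            return False
        if self.any_of_tags and not (tags & self.any_of_tags):
            return False
        if not self.required_flags <= flags:
            return False
        if self.disqualify_if_only and tags <= self.disqualify_if_only:
            return False
        return True


@dataclass
class TaxonomyMap:
    """An ordered collection of rules plus the meta-category allowlist.

    Order carries no semantics (labels are unioned over matching rules); it is
    preserved only so that a loaded file round-trips.
    """

    rules: List[TaxonomyRule] = field(default_factory=list)
    meta_allowlist: FrozenSet[str] = DEFAULT_META_ALLOWLIST

    def __post_init__(self):
        self.meta_allowlist = _norm_set(self.meta_allowlist)
        seen = set()
        for rule in self.rules:
            if rule.rule_id in seen:
                raise ValueError(f"duplicate rule_id: {rule.rule_id!r}")
            seen.add(rule.rule_id)


def default_taxonomy_path() -> Path:
    """Path of the taxonomy config shipped with the package."""
    return Path(__file__).parent / "data" / "default_taxonomy.yaml"


def _parse_rule(raw: dict, pos: int) -> TaxonomyRule:
    if not isinstance(raw, dict):
        raise ValueError(f"rule #{pos}: expected a mapping, got {type(raw).__name__}")
    rid = raw.get("rule_id")
    if not rid:
        raise ValueError(f"rule #{pos}: missing rule_id")
    emit_names = raw.get("emit") or []
    if not emit_names:
        raise ValueError(f"rule {rid!r}: emit must be a non-empty list")
    try:
        emit = frozenset(FoodClass.from_name(n) for n in emit_names)
    except ValueError as exc:
        raise ValueError(f"rule {rid!r}: {exc}") from exc
    known = {
        "rule_id",
        "emit",
        "required_meta",
        "any_of_tags",
        "disqualify_if_only",
        "required_flags",
    }
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"rule {rid!r}: unknown fields {sorted(unknown)}")
    return TaxonomyRule(
        rule_id=rid,
        emit=emit,
        required_meta=frozenset(raw.get("required_meta") or []),
        any_of_tags=frozenset(raw.get("any_of_tags") or []),
        disqualify_if_only=frozenset(raw.get("disqualify_if_only") or []),
        required_flags=frozenset(raw.get("required_flags") or []),
    )


def load_taxonomy(config_path: str | Path | None = None) -> TaxonomyMap:
    """Load a taxonomy rule set from a YAML config file.

    With no argument, loads the default rule set shipped with the package.
    Raises ``ValueError`` naming the offending rule on malformed input.
    """
    path = Path(config_path) if config_path is not None else default_taxonomy_path()
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: taxonomy config must be a mapping at top level")
    raw_rules = doc.get("rules") or []
    rules = [_parse_rule(r, i) for i, r in enumerate(raw_rules)]
    allow = doc.get("meta_allowlist")
    allowlist = frozenset(allow) if allow else DEFAULT_META_ALLOWLIST
    return TaxonomyMap(rules=rules, meta_allowlist=allowlist)


def save_taxonomy(tax: TaxonomyMap, config_path: str | Path) -> None:
    """Write a taxonomy rule set to YAML such that ``load`` round-trips."""
    doc = {
        "meta_allowlist": sorted(tax.meta_allowlist),
        "rules": [
            {
                "rule_id": r.rule_id,
                "emit": sorted(c.value for c in r.emit),
                "required_meta": sorted(r.required_meta),
                "any_of_tags": sorted(r.any_of_tags),
                "disqualify_if_only": sorted(r.disqualify_if_only),
                "required_flags": sorted(r.required_flags),
            }
            for r in tax.rules
        ],
    }
    with open(config_path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def map_record(record: StoreRecord, tax: TaxonomyMap) -> LabelSet:
    """Convert one record's surveyor tags and flags into a label set.

    Returns the union of emit sets over all matching rules; records whose
    meta category falls outside the allowlist get the empty label set.
    Unknown tags are simply ignored (no rule matches on them).
    """
    meta = _norm_token(record.meta_category)
    if meta not in tax.meta_allowlist:
        return frozenset()
    tags = _norm_set(record.tags)
    flags = _norm_set(record.flags)
    out: set = set()
    for rule in tax.rules:
        if rule.matches(meta, tags, flags):
            out |= rule.emit
    return frozenset(out)
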