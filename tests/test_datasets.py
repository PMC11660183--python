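"""Name normalization, modal deduplication and the leakage-controlled split."""

from __future__ import annotations

import datetime as dt
from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from foodenv.classes import FoodClass, labelset
from foodenv.datasets import (
    DatasetSplit,
    LabeledExample,
    deduplicate_modal,
    normalize_name,
    split_dataset,
)
from foodenv.records import StoreRecord


# --- normalize_name --------------------------------------------------------


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("JOHN'S", "john's"),
        ("La  Vina   Deli Grocery", "la vina deli grocery"),
        ("  Café ÉTOILE  ", "café étoile"),  # NBSP collapsed, NFKC kept accents
        ("Deli\tGrocery\nCo", "deli grocery co"),
    ],
)
def test_normalize_name(raw, expected):
    assert normalize_name(raw) == expected


@pytest.mark.parametrize("bad", ["", "   ", "\t\n"])
def test_normalize_rejects_blank(bad):
    with pytest.raises(ValueError):
        normalize_name(bad)


@settings(deadline=None, max_examples=200)
@given(st.text(min_size=1).filter(lambda s: s.strip()))
def test_normalize_is_idempotent(s):
    once = normalize_name(s)
    assert normalize_name(once) == once


# --- deduplicate_modal -----------------------------------------------------


def rec(name, record_id, survey=None):
    return StoreRecord(
        record_id=record_id, name=name, meta_category="Food",
        survey_date=survey or dt.date(2023, 1, 1),
    )


AB_R = labelset(FoodClass.ALCOHOL_BAR, FoodClass.RESTAURANT)
R = labelset(FoodClass.RESTAURANT)


def test_modal_labels_win():
    """Three surveys as bar+restaurant outvote one as restaurant only."""
    records = [
        (rec("John's", "r1"), AB_R),
        (rec("John's", "r2"), AB_R),
        (rec("John's", "r3"), AB_R),
        (rec("John's", "r4"), R),
    ]
    (example,) = deduplicate_modal(records)
    assert example.normalized_name == "john's"
    assert example.labels == AB_R
    assert set(example.provenance) == {"r1", "r2", "r3", "r4"}


def test_recency_breaks_frequency_ties():
    records = [
        (rec("John's", "r1", dt.date(2023, 1, 1)), R),
        (rec("John's", "r2", dt.date(2023, 2, 1)), R),
        (rec("John's", "r3", dt.date(2023, 3, 1)), AB_R),
        (rec("John's", "r4", dt.date(2023, 9, 1)), AB_R),  # most recent
    ]
    (example,) = deduplicate_modal(records)
    assert example.labels == AB_R


def test_record_id_breaks_remaining_ties():
    d = dt.date(2023, 5, 1)
    records = [(rec("John's", "r2", d), AB_R), (rec("John's", "r1", d), R)]
    (example,) = deduplicate_modal(records)
    assert example.labels == R  # r1 sorts before r2


def test_singleton_passes_through():
    (example,) = deduplicate_modal([(rec("Solo Cafe", "x1"), R)])
    assert example.labels == R


def _oracle_modal(group):
    """Brute-force mode with recency/record-id tie-break for one name."""
    counts = Counter(ls for _, ls in group)
    top = max(counts.values())
    tied = [ls for ls, c in counts.items() if c == top]
    if len(tied) == 1:
        return tied[0]
    best = None
    for r, ls in group:
        if ls not in tied:
            continue
        key = (-r.survey_date.toordinal(), r.record_id)
        if best is None or key < best[0]:
            best = (key, ls)
    return best[1]


_labelsets = st.sets(st.sampled_from(list(FoodClass)), max_size=3).map(frozenset)


@settings(deadline=None, max_examples=100)
@given(
    st.lists(
        st.tuples(
            st.sampled_from(["a", "b", "c"]),  # three distinct names
            _labelsets,
            st.dates(dt.date(2020, 1, 1), dt.date(2023, 12, 31)),
        ),
        min_size=1,
        max_size=10,
    )
)
def test_modal_dedup_matches_bruteforce_oracle(rows):
    records = [
        (rec(name, f"r{i}", survey), ls) for i, (name, ls, survey) in enumerate(rows)
    ]
    result = {e.normalized_name: e.labels for e in deduplicate_modal(records)}
    for name in {name for name, _, _ in rows}:
        group = [(r, ls) for r, ls in records if r.name == name]
        assert result[name] == _oracle_modal(group)


# --- split_dataset ---------------------------------------------------------


def make_examples(n):
    return [LabeledExample(f"store {i}", R) for i in range(n)]


def test_split_is_50_25_25():
    examples = make_examples(1000)
    counts = {e.normalized_name: 1 for e in examples}
    split = split_dataset(examples, counts, seed=3)
    assert (len(split.train), len(split.validation), len(split.test)) == (500, 250, 250)
    assert not split.memorized


def test_chains_are_memorized_into_train_only():
    examples = make_examples(40) + [LabeledExample("big chain", R)]
    counts = {e.normalized_name: 1 for e in examples}
    counts["big chain"] = 11
    split = split_dataset(examples, counts, seed=5)
    assert [e.normalized_name for e in split.memorized] == ["big chain"]
    train_names = {e.normalized_name for e in split.train}
    assert "big chain" in train_names
    for part in (split.validation, split.test):
        assert "big chain" not in {e.normalized_name for e in part}


def test_exactly_10_locations_is_not_a_chain():
    examples = make_examples(40)
    counts = {e.normalized_name: 1 for e in examples}
    counts["store 0"] = 10
    split = split_dataset(examples, counts, seed=5)
    assert not split.memorized


def test_split_deterministic_given_seed():
    examples = make_examples(101)
    counts = {e.normalized_name: 1 for e in examples}
    a = split_dataset(examples, counts, seed=9)
    b = split_dataset(examples, counts, seed=9)
    assert [e.normalized_name for e in a.train] == [e.normalized_name for e in b.train]
    assert [e.normalized_name for e in a.test] == [e.normalized_name for e in b.test]


def test_split_rejects_tiny_input():
    examples = make_examples(3)
    with pytest.raises(ValueError, match="at least 4"):
        split_dataset(examples, {e.normalized_name: 1 for e in examples}, seed=1)


@settings(deadline=None, max_examples=30)
@given(n=st.integers(4, 200), n_chains=st.integers(0, 5), seed=st.integers(0, 2**16))
def test_split_is_a_leak_free_partition(n, n_chains, seed):
    examples = make_examples(n + n_chains)
    counts = {e.normalized_name: 1 for e in examples}
    for i in range(n_chains):
        counts[f"store {i}"] = 11 + i
    split = split_dataset(examples, counts, seed=seed)
    names = [
        {e.normalized_name for e in part}
        for part in (split.train, split.validation, split.test)
    ]
    assert not (names[0] & names[1] or names[0] & names[2] or names[1] & names[2])
    # every example lands exactly once (memorized are inside train)
    assert sum(map(len, names)) == n + n_chains
    mem = {e.normalized_name for e in split.memorized}
    assert len(mem) == n_chains and mem <= names[0]
    # 50/25/25 within rounding on the non-memorized pool
    pool = n
    assert len(split.validation) == pool // 4
    assert len(split.test) == pool // 4


def test_dataset_split_invariants_enforced():
    ex = make_examples(4)
    with pytest.raises(ValueError, match="leak"):
        DatasetSplit(train=[ex[0]], validation=[ex[0]], test=[ex[1]])
    with pytest.raises(ValueError, match="memorized"):
        DatasetSplit(train=[ex[0]], validation=[ex[1]], test=[ex[2]], memorized=[ex[3]])
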