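"""Synthetic generators: consistency, calibration, determinism, planted truth."""

from __future__ import annotations

import math
from collections import Counter

import pytest

from foodenv.churn import build_hex_grid, mean_annual_change
from foodenv.classes import FoodClass
from foodenv.metrics import confusion_counts, summarize
from foodenv.synth import (
    PlantedChurn,
    SynthConfig,
    generate_directory,
    generate_longitudinal,
    generate_restaurant_dataset,
    token_lookup_labels,
)
from foodenv.io_utils import write_directory_csv
from foodenv.taxonomy import map_record


def test_tags_recover_ground_truth_exactly(world, taxonomy):
    """With no tag corruption, taxonomy mapping inverts the generator."""
    for rec, labels in world["pairs"]:
        assert map_record(rec, taxonomy) == labels


def test_name_lookup_recovers_ground_truth_at_zero_noise(world):
    """At noise 0 the longest-phrase token lookup is an exact inverse."""
    for rec, labels in world["pairs"]:
        assert token_lookup_labels(rec.name) == labels


def test_class_prevalence_is_calibrated():
    """Empirical Grocery prevalence within 3 binomial SE of the target."""
    p, n = 0.10, 10000
    cfg = SynthConfig(n_stores=n, n_chains=0, seed=123)
    cfg.class_prevalence[FoodClass.GROCERY] = p
    pairs = generate_directory(cfg)
    observed = sum(1 for _, ls in pairs if FoodClass.GROCERY in ls) / n
    se = math.sqrt(p * (1 - p) / n)
    assert abs(observed - p) <= 3 * se


def test_chains_replicate_names_at_11_plus_locations():
    cfg = SynthConfig(n_stores=500, n_chains=5, chain_size_range=(11, 20), seed=5)
    pairs = generate_directory(cfg)
    counts = Counter(rec.name for rec, _ in pairs)
    chains = {name: c for name, c in counts.items() if c >= 11}
    assert len(chains) == 5
    # Chain replicas sit at distinct locations and share one label set.
    by_name = {}
    for rec, ls in pairs:
        by_name.setdefault(rec.name, []).append((rec, ls))
    for name in chains:
        group = by_name[name]
        assert len({(r.longitude, r.latitude) for r, _ in group}) == len(group)
        assert len({ls for _, ls in group}) == 1


def test_directory_generation_is_deterministic(tmp_path):
    cfg = SynthConfig(n_stores=400, seed=99)
    a = generate_directory(cfg)
    b = generate_directory(SynthConfig(n_stores=400, seed=99))
    assert a == b
    pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
    write_directory_csv([r for r, _ in a], pa)
    write_directory_csv([r for r, _ in b], pb)
    assert pa.read_bytes() == pb.read_bytes()


def test_generated_records_satisfy_invariants(world):
    cfg = world["cfg"]
    for rec, labels in world["pairs"]:
        assert rec.name.strip()
        assert cfg.bbox.contains(rec.longitude, rec.latitude)
        assert list(rec.inspection_dates) == sorted(rec.inspection_dates)
        assert labels <= frozenset(FoodClass)


def test_infeasible_config_rejected():
    cfg = SynthConfig(n_stores=100, n_chains=0, seed=1)
    cfg.vocabulary[FoodClass.GROCERY] = ()
    with pytest.raises(ValueError, match="Grocery"):
        generate_directory(cfg)
    with pytest.raises(ValueError, match="chain_size_range"):
        SynthConfig(chain_size_range=(10, 12)).validate()


def test_lookup_f1_degrades_monotonically_with_noise():
    """Token-lookup macro-F1 is 1.0 noise-free and decreases with noise."""
    seeds = [11, 12, 13, 14, 15]
    means = []
    for noise in (0.0, 0.15, 0.3):
        f1s = []
        for seed in seeds:
            cfg = SynthConfig(n_stores=800, n_chains=0, noise_rate=noise, seed=seed)
            pairs = generate_directory(cfg)
            preds = [token_lookup_labels(r.name) for r, _ in pairs]
            actual = [ls for _, ls in pairs]
            f1s.append(summarize(confusion_counts(preds, actual)).macro_f1)
        means.append(sum(f1s) / len(f1s))
    assert means[0] == 1.0
    assert means[0] > means[1] > means[2]


# --- longitudinal ----------------------------------------------------------


def test_no_dynamics_when_closure_rate_zero():
    cfg = SynthConfig(n_stores=300, closure_rate=0.0, seed=21)
    pairs = generate_longitudinal(cfg)
    y0, y1 = cfg.year_range
    for rec, _ in pairs:
        assert rec.inspection_dates[0].year == y0
        assert rec.out_of_business_date is None
        assert rec.inspection_dates[-1].year == y1
    grid = build_hex_grid(cfg.bbox, cfg.grid_spacing_ft)
    cmap = mean_annual_change(pairs, grid, set(FoodClass), y0, y1)
    assert all(v == 0.0 for v in cmap.values.values())


@pytest.mark.parametrize("delta", [-2, 3])
def test_planted_churn_realized_exactly(delta):
    base = SynthConfig()
    grid = build_hex_grid(base.bbox, base.grid_spacing_ft)
    cell = sorted(grid.cells)[len(grid.cells) // 3]
    cfg = SynthConfig(
        n_stores=200,
        closure_rate=0.1,
        seed=31,
        planted_churn=[PlantedChurn(cell, frozenset({FoodClass.GROCERY}), delta)],
    )
    pairs = generate_longitudinal(cfg)
    y0, y1 = cfg.year_range
    # Consecutive-year differences in the planted cell equal the delta.
    for ya in range(y0, y1):
        cm = mean_annual_change(pairs, grid, {FoodClass.GROCERY}, ya, ya + 1)
        assert cm.count_y1[cell] - cm.count_y0[cell] == delta
    assert mean_annual_change(
        pairs, grid, {FoodClass.GROCERY}, y0, y1
    ).mean_annual_change_of(cell) == pytest.approx(delta)


def test_planted_cell_outside_grid_rejected():
    cfg = SynthConfig(
        n_stores=200,
        n_chains=0,
        seed=1,
        planted_churn=[PlantedChurn((9999, 9999), frozenset({FoodClass.GROCERY}), -1)],
    )
    with pytest.raises(ValueError, match="outside the grid"):
        generate_longitudinal(cfg)


def test_longitudinal_determinism():
    a = generate_longitudinal(SynthConfig(n_stores=150, seed=77))
    b = generate_longitudinal(SynthConfig(n_stores=150, seed=77))
    assert a == b


# --- restaurant extract ----------------------------------------------------


def test_restaurant_other_fraction_calibrated():
    n = 5000
    cfg = SynthConfig(n_stores=n, fraction_other=0.10, seed=41)
    records, _ = generate_restaurant_dataset(cfg)
    observed = sum(1 for r, _ in records if r.venue_tag == "Other") / n
    se = math.sqrt(0.10 * 0.90 / n)
    assert abs(observed - 0.10) <= 3 * se


def test_restaurant_no_other_when_fraction_zero():
    cfg = SynthConfig(n_stores=500, fraction_other=0.0, seed=42)
    records, true_venues = generate_restaurant_dataset(cfg)
    assert all(r.venue_tag != "Other" for r, _ in records)
    # observed venue equals the stored truth when nothing is masked
    assert all(r.venue_tag == true_venues[r.record_id] for r, _ in records)


def test_restaurant_labels_concentrate_on_prepared_food():
    cfg = SynthConfig(n_stores=400, seed=43)
    records, _ = generate_restaurant_dataset(cfg)
    allowed = {
        FoodClass.RESTAURANT,
        FoodClass.FAST_FOOD,
        FoodClass.ALCOHOL_BAR,
        FoodClass.JUICE_COFFEE,
        FoodClass.SWEETS_DESSERTS,
    }
    for _, labels in records:
        assert labels and labels <= allowed
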