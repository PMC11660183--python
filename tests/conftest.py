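"""Shared fixtures: a seeded synthetic world and a classifier trained on it."""

from __future__ import annotations

import pytest

from foodenv.classifier import StoreNameClassifier, TrainingConfig
from foodenv.datasets import deduplicate_modal, normalize_name, split_dataset
from foodenv.synth import SynthConfig, generate_directory
from foodenv.taxonomy import load_taxonomy

WORLD_SEED = 7


@pytest.fixture(scope="session")
def taxonomy():
    return load_taxonomy()


@pytest.fixture(scope="session")
def world():
    """2,000 noise-free labeled storefronts with dedup, split and counts."""
    cfg = SynthConfig(n_stores=2000, noise_rate=0.0, seed=WORLD_SEED)
    pairs = generate_directory(cfg)
    examples = deduplicate_modal(pairs)
    counts: dict = {}
    for rec, _ in pairs:
        key = normalize_name(rec.name)
        counts[key] = counts.get(key, 0) + 1
    split = split_dataset(examples, counts, seed=WORLD_SEED)
    return {"cfg": cfg, "pairs": pairs, "examples": examples, "counts": counts, "split": split}


@pytest.fixture(scope="session")
def fitted(world):
    """Reference classifier fitted on the session world."""
    model = StoreNameClassifier.from_split(
        world["split"], TrainingConfig(seed=WORLD_SEED)
    )
    return model.fit()
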