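# foodenv

Classify the retail food environment from storefront names.

Health departments and food-environment researchers routinely repurpose
administrative datasets — licensing extracts, inspection records, commercial
storefront directories — that carry store names and locations but no usable
food-retail categorization. `foodenv` implements a desk-scale version of that
categorization pipeline: store names are mapped onto ten **non-exclusive**
food-environment classes (a NYC bodega is simultaneously *Convenience* and
*Fast Food*), performance is reported with the sensitivity cutoff bands used
in the food-environment literature, and the resulting labels drive two
downstream products — hexbin churn maps of store openings/closings and
data-quality audits of independently tagged inspection files.

The ten classes, in fixed vector order: Specialty Foods, Convenience, Fast
Food, Discount, Grocery, Restaurant, Alcohol Store, Alcohol Bar, Juice/Coffee
Shops, Sweets and Desserts.

## What's in the box

- **`foodenv.taxonomy`** — a small rule language converting surveyor taxonomy
  fields (meta category, granular tags, `dine-in`/`quick-bites` flags) into
  label sets; rules only union labels, so mapping is order-independent and
  monotone in the tag set. A default YAML rule set ships with the package.
- **`foodenv.synth`** — synthetic storefront directories, longitudinal
  inspection extracts (with *planted*, exactly-recoverable per-hexbin churn)
  and restaurant tag files, all deterministic given a seed. Real storefront
  directories of this kind are licensed and cannot be redistributed; the
  generator stands in for them with known ground truth.
- **`foodenv.datasets`** — name normalization, modal deduplication (the most
  frequent full label combination per name wins; ties broken by survey
  recency, then record id) and a leakage-controlled 50/25/25 split in which
  chain names (>10 locations) are set aside into training only, so the model
  memorizes them without inflating held-out scores.
- **`foodenv.classifier`** — a multi-label store-name classifier with a
  statsmodels-style surface: `StoreNameClassifier(train, validation).fit()`
  returns a results object with per-class raw scores in [0, 1], 0.5
  thresholding, validation diagnostics and `summary()`. The reference backend
  is one-vs-rest logistic regression over word + character n-grams with early
  stopping on validation macro-F1 along a regularization path; a transformer
  backend is specified as a contract for GPU users.
- **`foodenv.metrics`** — per-class precision/recall/F1, pooled micro-F1
  `ΣTP / (ΣTP + ½(ΣFP + ΣFN))`, macro-F1 (arithmetic mean of per-class F1),
  and the six sensitivity bands (very poor < 0.20 … excellent ≥ 0.90).
- **`foodenv.churn`** — flat-top hexagonal binning with 2,640 ft (half-mile)
  centroid spacing and per-cell mean annual change in operating counts
  between two years, derived from inspection-date intervals; GeoJSON export.
- **`foodenv.dqe`** — agreement tables between classifier labels and external
  service/venue tags, imputation breakdowns for vague (`Other`) venue tags,
  and ranked discrepancy reports for manual review.
- **`foodenv.cli`** — `foodenv synth | build | train | predict | evaluate |
  churn | dqe`, thin wrappers over the library that write manifests alongside
  outputs.

## Worked example

```python
from foodenv import (
    StoreNameClassifier, SynthConfig, TrainingConfig,
    deduplicate_modal, generate_directory, normalize_name, split_dataset,
)

cfg = SynthConfig(n_stores=2000, noise_rate=0.0, seed=1)
pairs = generate_directory(cfg)                       # [(StoreRecord, labels)]
examples = deduplicate_modal(pairs)
counts = {}
for rec, _ in pairs:
    key = normalize_name(rec.name)
    counts[key] = counts.get(key, 0) + 1
split = split_dataset(examples, counts, seed=1)
results = StoreNameClassifier.from_split(split, TrainingConfig(seed=1)).fit()
report = results.evaluate(split.test)
print(f"micro-F1 {report.micro_f1:.3f}  macro-F1 {report.macro_f1:.3f}")
print(results.predictions_frame(["la vina deli grocery"]).filter(like="label_").T)
```

prints

```
micro-F1 0.992  macro-F1 0.990
                          0
label_SpecialtyFoods  False
label_Convenience      True
label_FastFood         True
label_Discount        False
label_Grocery         False
label_Restaurant      False
label_AlcoholStore    False
label_AlcoholBar      False
label_JuiceCoffee     False
label_SweetsDesserts  False
```

2,000 generated storefronts collapse to 1,534 unique names; five chain names
are memorized into training; the held-out macro-F1 of 0.990 reflects that the
noise-free synthetic world is (by design) almost perfectly separable from the
name alone — a bodega-style name such as "la vina deli grocery" correctly
receives *both* Convenience and Fast Food, and not Grocery.

The same label sets feed the spatial and audit stages:

```python
from foodenv import FoodClass, build_hex_grid, mean_annual_change
grid = build_hex_grid(cfg.bbox, spacing_ft=2640)
churn = mean_annual_change(longitudinal_pairs, grid,
                           {FoodClass.GROCERY, FoodClass.SPECIALTY_FOODS},
                           2019, 2021)
churn.save_geojson("grocery_churn.geojson")
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the whole pipeline from scratch on seeded synthetic data — directory
generation, dedup/split, training, held-out evaluation, a churn map with a
planted per-cell loss of 2 grocery stores/year (recovered exactly), and the
restaurant tag audit — printing a summary of each stage and writing the
results file.

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
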