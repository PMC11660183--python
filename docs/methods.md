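# Methods

This note documents the models and procedures implemented in `foodenv`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic data can and cannot establish.

## Problem setting

Administrative food datasets (licensing extracts, inspection records,
storefront directories) identify stores by name and point location but rarely
carry a categorization usable for food-environment analysis. The package
treats categorization as multi-label text classification of the store name
into ten food-retail classes. The classes are deliberately **not** mutually
exclusive: category membership is driven by overlapping attributes
(availability, price, service style), and common store types straddle
categories — the canonical example is the bodega, a corner store that is both
*Convenience* and *Fast Food*. A label is therefore a subset of the ten
classes, including the empty set (the store is not food retail, or no class
applies), and every prediction is a vector of ten independent scores in
[0, 1].

## Taxonomy mapping

Ground-truth labels originate in a surveyor taxonomy: a coarse meta category,
granular venue tags, and service flags. The published conversion is stated by
example, not as a grammar, so the package defines a minimal rule language
sufficient to express every stated mapping:

- `required_meta` — meta category must be in this set;
- `any_of_tags` — at least one tag shared;
- `required_flags` — all flags present (this carries the rule that
  restaurant-type tags yield *Restaurant* under `dine-in` and *Fast Food*
  under `quick-bites`, both labels when both flags are present);
- `disqualify_if_only` — the rule fails when the record's **entire** tag set
  is a subset of this set. This formalizes "grocery if tagged 'supermarket',
  but not if it *only* had the tag 'convenience store'".

Rules only union their emitted classes, which gives two useful invariants:
mapping is independent of rule order, and adding a tag to a record can never
remove a label (a superset of tags can only stop being a subset of a
disqualify set, never start). Tag/meta/flag matching is case-insensitive
after trimming, because administrative tags vary in casing. Records whose
meta category is outside the allowlist (`Food`, `Essentials`, `Drink`)
receive the empty label set.

The source vocabulary for six of the ten classes is proprietary and
unpublished; the shipped default config invents plausible tag lists for them
(marked non-canonical in the file) and is user-extensible. No attempt is made
to reconstruct the full vendor taxonomy.

## Dataset construction

**Normalization.** Names are NFKC-normalized, casefolded and
whitespace-collapsed; punctuation is retained (apostrophes are meaningful in
store names). Normalization is idempotent. Casefolding matches the use of an
uncased text encoder downstream.

**Modal deduplication.** Directories observe the same name many times. One
example is kept per normalized name, labeled with the *most frequent full
label combination* among its records (not per-class marginals — the
tie-break reasoning in the source conversion operates on whole multi-labels).
Frequency ties go to the label set of the most recently surveyed record;
residual ties break deterministically by ascending record id.

**Chain memorization.** Names with more than 10 distinct locations
(pre-dedup, counted after restriction to food meta categories; configurable)
are set aside before the split and appended to the training set only. This
exploits the memorization capacity of over-parameterized models: the model
learns chains by heart while held-out scores remain a lower bound on
inference performance, since no memorized name reaches validation or test.

**Split.** Remaining names are shuffled with the supplied seed and
partitioned 50/25/25 (floor rounding; the remainder goes to training, which
preserves the larger share). Name-disjointness across the three parts is
asserted at construction time.

## Classifier

The production-scale system this package mirrors fine-tunes an uncased
BERT-style encoder (Adam, learning rate 1e-6, beta1 0.9, beta2 0.999, early
stopping on validation macro-F1). GPU training and the licensed training data
are out of scope here, so `foodenv` ships a desk-scale **reference backend**
with the same contract and records the optimizer fields for a future
transformer backend (`backend='transformer'` raises `NotImplementedError`;
its train/predict signatures and uncased-text requirement are the contract).

The reference backend is one-vs-rest L2-regularized logistic regression over
TF-IDF features of word 1–2-grams and character 2–4-grams
(word-boundary-aware) of the normalized name. One-vs-rest is the right
decomposition because the target scores are independent per class and need
not sum to one. Early stopping maps onto a regularization path: checkpoints
at increasing C (0.01·C₀ … 1000·C₀, at most `max_epochs` of them) are each
evaluated on validation macro-F1; the best state is retained and the search
stops after `patience` (default 2) consecutive non-improving checkpoints. The
fitted model records a manifest (config, train-data hash, stopping point,
best validation macro-F1).

Numerical/degenerate choices:

- Thresholding is `score >= t` (inclusive at the boundary; the convention is
  asserted, not derivable) with default t = 0.5.
- A class with zero positive training examples degenerates to a constant-0
  scorer with a logged warning (not an error); all-positive degenerates to
  constant 1.
- Serialization is a single pickle whose bytes are reproducible given the
  same data and seed; a cached `id()`-based sklearn attribute is stripped at
  save time to keep files bit-identical across runs.

## Evaluation

Per class: precision TP/(TP+FP), recall TP/(TP+FN), F1 the harmonic mean
2pr/(p+r). All 0/0 ratios are defined as 0 with a logged warning. Macro-F1
is the arithmetic mean of the ten per-class F1 values; micro-F1 pools counts
across classes, ΣTP / (ΣTP + ½(ΣFP + ΣFN)). Micro pooling follows the
standard multi-label interpretation (class-example pairs pooled jointly).

Metric values map onto the six sensitivity bands used in the
food-environment classification literature. The printed cutoffs contain gaps
("< 20%", "21–30%", …, "> 90%"); they are resolved as contiguous half-open
intervals [0, .20) very poor, [.20, .30) poor, [.30, .50) fair, [.50, .71)
moderate, [.71, .90) good, [.90, 1] excellent — the unique contiguous
resolution consistent with all published in-text attributions (0.928
excellent, 0.616 moderate, 0.439 fair).

## Churn surfaces

Stores are binned into a flat-top hexagonal grid whose adjacent centroids are
2,640 ft (half a mile, about a ten-minute walk) apart; a custom equal-cell
geography limits modifiable-areal-unit effects relative to administrative
boundaries. Centroids sit on the axial lattice x = 1.5Rq, y = √3·R(r + q/2)
with circumradius R = spacing/√3, so hexagons are exactly the Voronoi cells
of the centroids and point assignment (cube-rounded axial coordinates) equals
nearest-centroid assignment.

A store's evident operating interval runs from its first inspection date to
its recorded out-of-business date (or last inspection date if open); it
operates in calendar year y iff the interval intersects that year. Records
without inspection dates are excluded with a warning. Per cell and class
group, churn is

    mean_annual_change = (count_y1 − count_y0) / (y1 − y0),

the endpoint difference over the span — identical, by telescoping, to the
mean of consecutive annual differences, which is why no per-year formula is
needed. Class-group membership is label-set **intersection**: a
Grocery+Convenience store counts in maps of either group, mirroring
non-exclusive classes. Distinct storefronts (record ids) are counted; no
per-cell name deduplication is applied.

Coordinates: inputs are WGS84; binning happens in a local equirectangular
projection in US feet about the grid origin (`crs_id='local-feet'`).
Full EPSG machinery is intentionally not a dependency; at city scale
(< ~50 km) the projection's distance distortion is far below the cell size.
Geographic CRS identifiers are rejected with instructions to use a projected
frame.

## Data-quality enhancement

Given an externally tagged restaurant file and classifier labels for the same
records, the module (i) cross-tabulates labels against the service
description or venue tag, restricted to a class set (default
{Fast Food, Restaurant}; records labeled only Sweets/Desserts or Juice/Coffee
are excluded to avoid unwanted overlap — a bubble-tea shop tagged 'Takeout'
is not a restaurant disagreement); (ii) buckets vague 'Other' venue records
by what the model inferred (restaurant without bar / with bar / other class /
unlabeled — fractions sum to 1); and (iii) ranks contradictions between
labels and a user-supplied tag→expected-class alignment by count for manual
review. Multi-label records count once per held restricted class. The module
reports; it never rewrites source tags.

## Synthetic data: the stated world

The generator emulates the three proprietary inputs with known ground truth.

**Label model.** Co-occurrence pairs (default: the bodega pair
Convenience∧FastFood at joint probability 0.05) fire independently and force
both members; every class is then drawn with a conditional probability
adjusted so its **marginal** prevalence equals the configured value exactly
(binomial calibration is a test contract). Default prevalences are
NYC-plausible shares chosen once (Restaurant .25, Fast Food .20, Convenience
.14, Grocery .10, Alcohol Bar / Juice-Coffee / Sweets .08, Specialty .06,
Alcohol Store .05, Discount .04). A draw can come up empty (~1/3 of stores
under the defaults): such storefronts are emitted as non-food retail with a
meta category outside the allowlist — mirroring the fact that a raw directory
snapshot contains all retail and is *restricted* to food meta categories
during preprocessing.

**Name grammar.** `<proper noun> <one token per held class> [suffix]`, with
class token phrases chosen pairwise distinct so that a longest-phrase token
lookup inverts the grammar exactly; bodega-type stores instead draw "deli
grocery"-style patterns (multi-label names in the style of 'la vina deli
grocery'). With probability `noise_rate` the name carries no class token
(person/place tokens only). Token draws that would accidentally spell a
bodega pattern (FastFood 'deli' + Grocery 'grocery') are redrawn. Surveyor
tags/flags are emitted consistently with the ground truth, so taxonomy
mapping recovers labels exactly when tag corruption is 0. Chains replicate
one name with one label set at 11–20 distinct locations (5 chains by
default).

**Longitudinal extract.** Background stores operate from the first year of
the window (2019–2021 by default), one inspection per operating year,
closures geometric at `closure_rate` (default 5%/yr, a plausible retail
exit rate). Planted churn deltas are realized *exactly* as staircases of
openings (positive) or closings (negative) at the target cell's centroid;
background stores are kept out of planted cells so recovery is exact, not
statistical.

**Restaurant file.** Labels concentrate on the five prepared-food classes;
service descriptions derive from labels (vague with probability 0.10), venue
tags derive deterministically from labels, and a configurable fraction
(default 0.10, matching the observed share of vague venue tags) is masked to
'Other' with the true venue retained for recovery testing.

**What a green test does not establish.** The generator does not model
realistic name distributions (real store names are far noisier than the
token grammar), spatial clustering (placement is uniform in the bbox),
borough geography, survey error, or time-varying prevalence. Near-perfect
synthetic F1 therefore validates the *pipeline mechanics* — leakage control,
multi-label handling, memorization, metric arithmetic, exact churn
accounting — not real-world classification difficulty; the published
real-data scores (macro-F1 ≈ 0.71) are the realistic operating point.

## Known limitations

- The reference backend is a bag-of-n-grams model; it cannot capture the
  semantic generalization a fine-tuned encoder provides ("Oak and Steel" →
  alcohol) beyond surface token statistics.
- The local-feet projection is inappropriate for regions spanning several
  degrees; a projected-CRS backend would be needed for continental extents.
- Churn counts treat each record id as one storefront; duplicate listings of
  one physical store inflate counts, as they would in the source data.
- The default taxonomy config covers the published rules plus invented
  vocabulary; applying it to a real directory requires extending the rule
  file to that vendor's tag set.
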