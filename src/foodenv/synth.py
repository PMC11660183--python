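"""Synthetic storefront data with known ground truth.

The real datasets this pipeline was designed around (a licensed ground-truthed
storefront directory, a state longitudinal inspection extract, and a city
restaurant-inspection file) are proprietary and cannot be shipped. This
module generates stand-ins with the statistical structure the pipeline
assumes, so every stage is testable end to end:

* :func:`generate_directory` — a labeled directory. Store names are composed
  from class-conditional token grammars ("<proper noun> <class tokens>
  [suffix]"), so the name signals the class; multi-label stores concatenate
  one token per held class, and bodega-type stores (the planted
  Convenience ∧ FastFood co-occurrence) draw "deli grocery" patterns. With
  probability ``noise_rate`` a name carries no class-indicative token at all.
  Surveyor tags and flags are emitted consistently with the ground-truth
  labels, so taxonomy mapping recovers them exactly when tag corruption is 0.
  Chains replicate one name at >= 11 distinct locations.
* :func:`generate_longitudinal` — an inspection extract with one or more
  inspection dates per operating year, closures, and optionally *planted
  churn*: per-hexbin year-over-year count deltas realized exactly so the
  churn stage can be verified against constructed ground truth.
* :func:`generate_restaurant_dataset` — a restaurant file with
  service-description and venue tags, including vague tags and a configurable
  fraction of 'Other' venue tags whose true venue is retained for
  imputation-recovery tests.

Everything is deterministic given the config seed. Geographic sampling is
uniform within the bounding box; realistic spatial clustering is out of
scope (churn correctness is tested through planted deltas instead).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .churn import BBox, HexGrid, build_hex_grid
from .classes import FoodClass, LabelSet
from .records import StoreRecord

__all__ = [
    "SynthConfig",
    "PlantedChurn",
    "generate_directory",
    "generate_longitudinal",
    "generate_restaurant_dataset",
    "token_lookup_labels",
    "DEFAULT_NAME_VOCABULARY",
    "BODEGA_NAME_PATTERNS",
]

# ---------------------------------------------------------------------------
# Default stated world
# ---------------------------------------------------------------------------

#: Class-conditional name tokens. Phrases are class-distinct so that, absent
#: noise, a longest-phrase token lookup recovers the label set exactly.
DEFAULT_NAME_VOCABULARY: Dict[FoodClass, Tuple[str, ...]] = {
    FoodClass.SPECIALTY_FOODS: (
        "cheese shop", "butcher", "seafood", "spice emporium", "health nook",
    ),
    FoodClass.CONVENIENCE: ("convenience", "mini mart", "corner store"),
    FoodClass.FAST_FOOD: (
        "deli", "burgers", "pizza", "fried chicken", "sandwich shop",
    ),
    FoodClass.DISCOUNT: ("99 cents", "dollar store", "bargain depot"),
    FoodClass.GROCERY: ("grocery", "supermarket", "fresh market"),
    FoodClass.RESTAURANT: ("restaurant", "bistro", "trattoria", "steakhouse"),
    FoodClass.ALCOHOL_STORE: ("wines & spirits", "liquors", "bottle shop"),
    FoodClass.ALCOHOL_BAR: ("bar", "tavern", "pub", "lounge"),
    FoodClass.JUICE_COFFEE: ("coffee", "juice bar", "cafe", "tea room"),
    FoodClass.SWEETS_DESSERTS: ("bakery", "ice cream", "donuts", "sweets"),
}

#: Name patterns for bodega-type stores (Convenience ∧ FastFood).
BODEGA_NAME_PATTERNS: Tuple[str, ...] = (
    "deli grocery", "deli & grocery", "gourmet deli mart",
)

_BODEGA_LABELS = frozenset({FoodClass.CONVENIENCE, FoodClass.FAST_FOOD})

_PROPER_NOUNS = (
    "la vina", "golden", "sunset", "lucky", "royal", "liberty", "empire",
    "atlantic", "bedford", "crown heights", "flushing", "astoria", "fordham",
    "tremont", "jackson", "marcy", "nostrand", "utica", "bay ridge",
    "greenpoint", "ridgewood", "soundview", "kingsbridge", "canarsie",
    "bensonhurst", "elmhurst", "woodside", "parkchester", "harlem",
    "red hook", "gowanus", "mott haven", "hunts point", "brighton",
    "midwood", "rosedale", "laurelton", "bayside", "maspeth", "corona",
)

_PERSON_NAMES = (
    "john's", "maria's", "ahmed's", "wei's", "olga's", "carlos's", "fatima's",
    "ivan's", "priya's", "kofi's", "rosa's", "dmitri's", "amara's", "luis's",
    "chen's", "yusuf's", "nadia's", "marco's", "keisha's", "stavros's",
)

_GENERIC_SUFFIXES = ("", "", "", "express", "plus", "& co", "ii")

#: Tokens for names that carry no class signal (the noise component).
_NOISE_TOKENS = ("place", "corner", "spot", "house", "stop", "hub")

#: Canonical surveyor tag emitted per ground-truth class (goods classes).
_CANONICAL_TAGS: Dict[FoodClass, str] = {
    FoodClass.SPECIALTY_FOODS: "cheese shop",
    FoodClass.CONVENIENCE: "convenience store",
    FoodClass.DISCOUNT: "dollar store",
    FoodClass.GROCERY: "supermarket",
    FoodClass.ALCOHOL_STORE: "liquor store",
    FoodClass.ALCOHOL_BAR: "bar",
    FoodClass.JUICE_COFFEE: "coffee shop",
    FoodClass.SWEETS_DESSERTS: "bakery",
}

_RESTAURANT_TYPE_TAGS = (
    "kosher delicatessen", "bagel shop", "pizzeria", "taqueria", "french cafe",
    "diner", "deli", "sandwich shop", "burger joint", "gyro shop",
    "fried chicken restaurant",
)

_DRINK_ONLY = frozenset(
    {FoodClass.ALCOHOL_STORE, FoodClass.ALCOHOL_BAR, FoodClass.JUICE_COFFEE}
)

#: NYC-plausible prevalences used when none are supplied (sum > 1 is fine:
#: classes are not exclusive).
DEFAULT_PREVALENCE: Dict[FoodClass, float] = {
    FoodClass.SPECIALTY_FOODS: 0.06,
    FoodClass.CONVENIENCE: 0.14,
    FoodClass.FAST_FOOD: 0.20,
    FoodClass.DISCOUNT: 0.04,
    FoodClass.GROCERY: 0.10,
    FoodClass.RESTAURANT: 0.25,
    FoodClass.ALCOHOL_STORE: 0.05,
    FoodClass.ALCOHOL_BAR: 0.08,
    FoodClass.JUICE_COFFEE: 0.08,
    FoodClass.SWEETS_DESSERTS: 0.08,
}

#: Approximate five-borough bounding box.
DEFAULT_BBOX = BBox(-74.26, 40.49, -73.70, 40.92)

_RESTAURANT_SERVICE_TAGS: Dict[FoodClass, Tuple[str, ...]] = {
    FoodClass.RESTAURANT: ("Fine Dining", "Sit-down Service", "Family Style"),
    FoodClass.FAST_FOOD: ("Fast Food", "Takeout (To Go/Grab-And-Go only)", "Counter Service"),
}

VAGUE_SERVICE_TAGS = ("Other", "Not Applicable", "Delivery only", "Caterer")


@dataclass(frozen=True)
class PlantedChurn:
    """An exact per-hexbin annual count delta to realize in the output."""

    cell: Tuple[int, int]
    class_group: FrozenSet[FoodClass]
    delta_per_year: int

    def __post_init__(self):
        object.__setattr__(self, "class_group", frozenset(self.class_group))
        if not self.class_group:
            raise ValueError("planted churn class_group must be non-empty")
        if self.delta_per_year == 0:
            raise ValueError("planted delta must be nonzero")


@dataclass
class SynthConfig:
    """The stated world of the synthetic generators.

    Defaults match the desk-scale evaluation scenario: 2,000 stores, five
    chains of 11–20 locations, a 5% bodega co-occurrence, noise-free names,
    the 2019–2021 year window and a 5%/year closure rate over an
    NYC-footprint bounding box.
    """

    n_stores: int = 2000
    class_prevalence: Dict[FoodClass, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    cooccurrence_pairs: List[Tuple[FoodClass, FoodClass, float]] = field(
        default_factory=lambda: [
            (FoodClass.CONVENIENCE, FoodClass.FAST_FOOD, 0.05)
        ]
    )
    n_chains: int = 5
    chain_size_range: Tuple[int, int] = (11, 20)
    noise_rate: float = 0.0
    tag_corruption_rate: float = 0.0
    vocabulary: Dict[FoodClass, Tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_NAME_VOCABULARY)
    )
    bbox: BBox = DEFAULT_BBOX
    year_range: Tuple[int, int] = (2019, 2021)
    closure_rate: float = 0.05
    planted_churn: List[PlantedChurn] = field(default_factory=list)
    grid_spacing_ft: float = 2640.0
    fraction_other: float = 0.10
    vague_service_rate: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        probs = list(self.class_prevalence.values()) + [
            self.noise_rate,
            self.tag_corruption_rate,
            self.closure_rate,
            self.fraction_other,
            self.vague_service_rate,
        ] + [p for _, _, p in self.cooccurrence_pairs]
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.n_stores < 1:
            raise ValueError("n_stores must be positive")
        lo, hi = self.chain_size_range
        if lo < 11 or hi < lo:
            raise ValueError(
                "chain_size_range minimum must be >= 11 (a chain has more "
                "than 10 locations) and the interval non-empty"
            )
        for c, p in self.class_prevalence.items():
            if p > 0 and not self.vocabulary.get(c):
                raise ValueError(
                    f"class {c.value} has prevalence {p} but an empty name vocabulary"
                )
        for a, b, pj in self.cooccurrence_pairs:
            for c in (a, b):
                if self.class_prevalence.get(c, 0.0) < pj:
                    raise ValueError(
                        f"co-occurrence joint probability {pj} exceeds the "
                        f"marginal prevalence of {c.value}"
                    )
        if self.n_chains > 0 and self.n_stores < self.n_chains * hi + 4:
            raise ValueError(
                "n_stores too small to host the configured chains plus "
                "non-chain stores"
            )


# ---------------------------------------------------------------------------
# Label and name sampling
# ---------------------------------------------------------------------------


def _forced_probability(cfg: SynthConfig, c: FoodClass) -> float:
    """Probability that some co-occurrence event forces class ``c`` on."""
    keep = 1.0
    for a, b, pj in cfg.cooccurrence_pairs:
        if c in (a, b):
            keep *= 1.0 - pj
    return 1.0 - keep


def _sample_labels(cfg: SynthConfig, rng: np.random.Generator) -> Tuple[LabelSet, bool]:
    """Draw one ground-truth label set; returns (labels, is_bodega).

    Each co-occurrence pair independently fires with its joint probability and
    forces both members on; every class is then drawn with a conditional
    probability adjusted so its *marginal* prevalence equals the configured
    value exactly (the binomial calibration contract). The draw may come up
    empty: such a storefront is non-food (the caller gives it a meta category
    outside the allowlist and a class-free name).
    """
    labels: Set[FoodClass] = set()
    is_bodega = False
    for a, b, pj in cfg.cooccurrence_pairs:
        if rng.random() < pj:
            labels |= {a, b}
            if frozenset({a, b}) == _BODEGA_LABELS:
                is_bodega = True
    for c, p in cfg.class_prevalence.items():
        if p <= 0 or c in labels:
            continue
        forced = _forced_probability(cfg, c)
        q = (p - forced) / (1.0 - forced) if forced < 1.0 else 0.0
        if q > 0 and rng.random() < q:
            labels.add(c)
    return frozenset(labels), is_bodega


def _compose_name(
    labels: LabelSet,
    is_bodega: bool,
    noisy: bool,
    cfg: SynthConfig,
    rng: np.random.Generator,
) -> str:
    prefix = (
        _PERSON_NAMES[rng.integers(len(_PERSON_NAMES))]
        if rng.random() < 0.35
        else _PROPER_NOUNS[rng.integers(len(_PROPER_NOUNS))]
    )
    if noisy or not labels:
        token = _NOISE_TOKENS[rng.integers(len(_NOISE_TOKENS))]
        return f"{prefix} {token}".strip()
    if is_bodega:
        pattern = BODEGA_NAME_PATTERNS[rng.integers(len(BODEGA_NAME_PATTERNS))]
        extras = [
            cfg.vocabulary[c][rng.integers(len(cfg.vocabulary[c]))]
            for c in sorted(labels - _BODEGA_LABELS, key=lambda c: c.index)
        ]
        body = " ".join([pattern] + extras)
    else:
        # Re-draw tokens if their concatenation accidentally spells a bodega
        # pattern (e.g. FastFood 'deli' + Grocery 'grocery'), which would make
        # the name ambiguous with the planted co-occurrence grammar.
        for _ in range(50):
            parts = []
            for c in sorted(labels, key=lambda c: c.index):
                vocab = cfg.vocabulary[c]
                parts.append(vocab[rng.integers(len(vocab))])
            body = " ".join(parts)
            if not any(pat in body for pat in BODEGA_NAME_PATTERNS):
                break
    suffix = _GENERIC_SUFFIXES[rng.integers(len(_GENERIC_SUFFIXES))]
    return " ".join(x for x in (prefix, body, suffix) if x)


def _tags_and_flags(
    labels: LabelSet, rng: np.random.Generator
) -> Tuple[Set[str], Set[str]]:
    """Surveyor tags/flags consistent with the ground-truth label set."""
    tags: Set[str] = set()
    flags: Set[str] = set()
    for c in labels:
        if c in _CANONICAL_TAGS:
            tags.add(_CANONICAL_TAGS[c])
    if FoodClass.RESTAURANT in labels or FoodClass.FAST_FOOD in labels:
        tags.add(_RESTAURANT_TYPE_TAGS[rng.integers(len(_RESTAURANT_TYPE_TAGS))])
        if FoodClass.RESTAURANT in labels:
            flags.add("dine-in")
        if FoodClass.FAST_FOOD in labels:
            flags.add("quick-bites")
    return tags, flags


_NON_FOOD_METAS = ("Apparel", "Home Goods", "Services")


def _meta_for(labels: LabelSet, rng: np.random.Generator) -> str:
    # Stores with no food class are non-food retail captured by the directory
    # snapshot; their meta category falls outside the Food/Essentials/Drink
    # allowlist, so taxonomy mapping returns the empty label set for them.
    if not labels:
        return _NON_FOOD_METAS[rng.integers(len(_NON_FOOD_METAS))]
    if labels <= _DRINK_ONLY:
        return "Drink"
    return "Food"


def _random_point(
    cfg: SynthConfig,
    rng: np.random.Generator,
    avoid: Optional[Tuple[HexGrid, Set[Tuple[int, int]]]] = None,
) -> Tuple[float, float]:
    bbox = cfg.bbox
    for _ in range(1000):
        lon = rng.uniform(bbox.min_lon, bbox.max_lon)
        lat = rng.uniform(bbox.min_lat, bbox.max_lat)
        if avoid is None:
            return lon, lat
        grid, cells = avoid
        if grid.cell_of(lon, lat) not in cells:
            return lon, lat
    raise ValueError("could not place a store outside the planted cells")


def _random_date(year: int, rng: np.random.Generator) -> dt.date:
    return dt.date(year, 1, 1) + dt.timedelta(days=int(rng.integers(0, 365)))


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def generate_directory(
    cfg: SynthConfig,
) -> List[Tuple[StoreRecord, LabelSet]]:
    """Generate a labeled storefront directory.

    Returns one ``(record, ground_truth_labels)`` pair per storefront. The
    first stores are chain replicas: each of the ``n_chains`` chains repeats
    one name (with one fixed label set) at 11+ distinct locations. Total
    record count is exactly ``n_stores``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    out: List[Tuple[StoreRecord, LabelSet]] = []
    used_names: Set[str] = set()
    idx = 0

    def make_record(name: str, labels: LabelSet) -> StoreRecord:
        nonlocal idx
        tags, flags = _tags_and_flags(labels, rng)
        if cfg.tag_corruption_rate > 0 and rng.random() < cfg.tag_corruption_rate:
            tags, flags = set(), set()
        lon, lat = _random_point(cfg, rng)
        year = int(rng.integers(cfg.year_range[0], cfg.year_range[1] + 1))
        rec = StoreRecord(
            record_id=f"S{idx:06d}",
            name=name,
            meta_category=_meta_for(labels, rng),
            tags=frozenset(tags),
            flags=frozenset(flags),
            survey_date=_random_date(year, rng),
            longitude=lon,
            latitude=lat,
        )
        idx += 1
        return rec

    lo, hi = cfg.chain_size_range
    for _ in range(cfg.n_chains):
        labels, is_bodega = _sample_labels(cfg, rng)
        name = _compose_name(labels, is_bodega, False, cfg, rng)
        while name in used_names:  # chain names must be distinct
            name = _compose_name(labels, is_bodega, False, cfg, rng)
        used_names.add(name)
        size = int(rng.integers(lo, hi + 1))
        for _ in range(size):
            out.append((make_record(name, labels), labels))

    while len(out) < cfg.n_stores:
        labels, is_bodega = _sample_labels(cfg, rng)
        noisy = rng.random() < cfg.noise_rate
        name = _compose_name(labels, is_bodega, noisy, cfg, rng)
        if name in used_names:
            continue  # keep chain names exclusive to their chain
        out.append((make_record(name, labels), labels))
    return out


def generate_longitudinal(
    cfg: SynthConfig,
) -> List[Tuple[StoreRecord, LabelSet]]:
    """Generate a longitudinal inspection extract with optional planted churn.

    Background stores operate from the first year of ``year_range`` and
    receive one inspection date per operating year; closures are sampled at
    ``closure_rate`` per year and recorded as an out-of-business date.
    Planted churn deltas are realized exactly: the planted cells contain only
    purpose-built stores whose openings/closings change the cell's operating
    count by ``delta_per_year`` between every pair of consecutive years, and
    background stores are kept out of those cells.
    """
    cfg.validate()
    y_start, y_end = cfg.year_range
    if y_end - y_start < 2:
        raise ValueError("year_range must span at least 3 calendar years")
    rng = np.random.default_rng(cfg.seed)
    grid = build_hex_grid(cfg.bbox, cfg.grid_spacing_ft)
    planted_cells = {p.cell for p in cfg.planted_churn}
    for p in cfg.planted_churn:
        if p.cell not in grid.cells:
            raise ValueError(f"planted cell {p.cell} is outside the grid")
        if abs(p.delta_per_year) * (y_end - y_start) > cfg.n_stores:
            raise ValueError("planted churn exceeds available stores")

    out: List[Tuple[StoreRecord, LabelSet]] = []
    idx = 0

    def longitudinal_record(
        name: str,
        labels: LabelSet,
        lon: float,
        lat: float,
        first_year: int,
        last_year: int,
        closes: bool,
    ) -> StoreRecord:
        nonlocal idx
        inspections = [
            dt.date(y, int(rng.integers(1, 12)), int(rng.integers(1, 28)))
            for y in range(first_year, last_year + 1)
        ]
        inspections.sort()
        oob = None
        if closes:
            oob = max(
                inspections[-1],
                dt.date(last_year, 12, int(rng.integers(1, 29))),
            )
        tags, flags = _tags_and_flags(labels, rng)
        rec = StoreRecord(
            record_id=f"L{idx:06d}",
            name=name,
            meta_category=_meta_for(labels, rng),
            tags=frozenset(tags),
            flags=frozenset(flags),
            survey_date=inspections[0],
            longitude=lon,
            latitude=lat,
            inspection_dates=tuple(inspections),
            out_of_business_date=oob,
        )
        idx += 1
        return rec

    avoid = (grid, planted_cells) if planted_cells else None
    for _ in range(cfg.n_stores):
        labels, is_bodega = _sample_labels(cfg, rng)
        noisy = rng.random() < cfg.noise_rate
        name = _compose_name(labels, is_bodega, noisy, cfg, rng)
        lon, lat = _random_point(cfg, rng, avoid=avoid)
        last_year = y_end
        closes = False
        if cfg.closure_rate > 0:
            for y in range(y_start, y_end + 1):
                if rng.random() < cfg.closure_rate:
                    last_year, closes = y, True
                    break
        out.append(
            (
                longitudinal_record(
                    name, labels, lon, lat, y_start, last_year, closes
                ),
                labels,
            )
        )

    # Planted stores: exact staircase of openings (delta>0) or closings
    # (delta<0) at the cell centroid.
    span = y_end - y_start
    for p in cfg.planted_churn:
        labels = frozenset(p.class_group)
        cx, cy = grid.cells[p.cell]
        lon, lat = grid.projection.to_lonlat(cx, cy)
        k = abs(p.delta_per_year)
        for j in range(1, span + 1):
            for _ in range(k):
                name = _compose_name(labels, False, False, cfg, rng)
                if p.delta_per_year < 0:
                    first, last, closes = y_start, y_start + j - 1, True
                else:
                    first, last, closes = y_start + j, y_end, False
                out.append(
                    (
                        longitudinal_record(
                            name, labels, lon, lat, first, last, closes
                        ),
                        labels,
                    )
                )
    return out


def generate_restaurant_dataset(
    cfg: SynthConfig,
) -> Tuple[List[Tuple[StoreRecord, LabelSet]], Dict[str, str]]:
    """Generate a restaurant inspection file with service/venue tags.

    Label sets concentrate on the prepared-food classes (Restaurant, Fast
    Food, Alcohol Bar, Juice/Coffee, Sweets and Desserts). Each record gets a
    service description (vague with probability ``vague_service_rate``) and a
    venue tag derived from its labels; with probability ``fraction_other``
    the venue tag is replaced by 'Other'. Returns the records and a map
    record_id -> true venue for every record (for recovery testing).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    resto_classes = (
        FoodClass.RESTAURANT,
        FoodClass.FAST_FOOD,
        FoodClass.ALCOHOL_BAR,
        FoodClass.JUICE_COFFEE,
        FoodClass.SWEETS_DESSERTS,
    )
    prev = {c: cfg.class_prevalence.get(c, 0.0) for c in resto_classes}
    if not any(prev.values()):
        raise ValueError("no prepared-food class has positive prevalence")

    out: List[Tuple[StoreRecord, LabelSet]] = []
    true_venues: Dict[str, str] = {}
    for i in range(cfg.n_stores):
        labels = frozenset(
            c for c, p in prev.items() if p > 0 and rng.random() < p
        )
        if not labels:
            classes = [c for c, p in prev.items() if p > 0]
            weights = np.array([prev[c] for c in classes])
            labels = frozenset(
                {classes[rng.choice(len(classes), p=weights / weights.sum())]}
            )
        noisy = rng.random() < cfg.noise_rate
        name = _compose_name(labels, False, noisy, cfg, rng)

        if rng.random() < cfg.vague_service_rate:
            service = VAGUE_SERVICE_TAGS[rng.integers(len(VAGUE_SERVICE_TAGS))]
        elif FoodClass.FAST_FOOD in labels:
            opts = _RESTAURANT_SERVICE_TAGS[FoodClass.FAST_FOOD]
            service = opts[rng.integers(len(opts))]
        elif FoodClass.RESTAURANT in labels:
            opts = _RESTAURANT_SERVICE_TAGS[FoodClass.RESTAURANT]
            service = opts[rng.integers(len(opts))]
        else:
            service = VAGUE_SERVICE_TAGS[rng.integers(len(VAGUE_SERVICE_TAGS))]

        venue = _venue_for(labels)
        true_venues_id = f"R{i:06d}"
        true_venues[true_venues_id] = venue
        observed_venue = (
            "Other" if rng.random() < cfg.fraction_other else venue
        )
        lon, lat = _random_point(cfg, rng)
        year = int(rng.integers(cfg.year_range[0], cfg.year_range[1] + 1))
        rec = StoreRecord(
            record_id=true_venues_id,
            name=name,
            meta_category="Food",
            tags=frozenset(),
            flags=frozenset(),
            survey_date=_random_date(year, rng),
            longitude=lon,
            latitude=lat,
            service_description=service,
            venue_tag=observed_venue,
        )
        out.append((rec, labels))
    return out, true_venues


def _venue_for(labels: LabelSet) -> str:
    has_resto = FoodClass.RESTAURANT in labels or FoodClass.FAST_FOOD in labels
    has_bar = FoodClass.ALCOHOL_BAR in labels
    if has_resto and has_bar:
        return "Restaurant (with Bar)"
    if has_resto:
        return "Restaurant (no bar)"
    if has_bar:
        return "Bar/Tavern/Lounge"
    if FoodClass.JUICE_COFFEE in labels:
        return "Coffee House"
    return "Bakery/Dessert Shop"


# ---------------------------------------------------------------------------
# Token-lookup reference classifier (used as an oracle in tests)
# ---------------------------------------------------------------------------


def token_lookup_labels(
    name: str,
    vocabulary: Optional[Mapping[FoodClass, Sequence[str]]] = None,
) -> LabelSet:
    """Recover labels from a generated name by longest-phrase token lookup.

    Matches class token phrases (and bodega patterns, which emit Convenience
    and FastFood) against the name longest-first on word boundaries,
    consuming matched words so that e.g. the 'deli grocery' bodega pattern is
    not also read as a Grocery token. This is the trivially correct inverse
    of the name grammar at noise 0, used as an independent oracle.
    """
    vocab = vocabulary or DEFAULT_NAME_VOCABULARY
    phrases: List[Tuple[str, FrozenSet[FoodClass]]] = [
        (p, _BODEGA_LABELS) for p in BODEGA_NAME_PATTERNS
    ]
    for c, toks in vocab.items():
        phrases.extend((t, frozenset({c})) for t in toks)
    phrases.sort(key=lambda item: -len(item[0].split()))
    words = name.lower().split()
    consumed = [False] * len(words)
    labels: Set[FoodClass] = set()
    for phrase, emitted in phrases:
        pw = phrase.lower().split()
        n = len(pw)
        for i in range(len(words) - n + 1):
            if any(consumed[i : i + n]):
                continue
            if words[i : i + n] == pw:
                labels |= emitted
                for j in range(i, i + n):
                    consumed[j] = True
    return frozenset(labels)
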