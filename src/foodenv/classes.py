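"""The ten food-environment retail classes and label-set utilities.

The classes partition the retail food environment from a public-health
perspective and are deliberately **not** mutually exclusive: a NYC bodega is
simultaneously a convenience store and a deli counter (fast food), so a store
carries a *set* of labels. The enumeration order below is fixed and defines
the vector index used by every label vector and score vector in the package.
"""

from __future__ import annotations

import enum
from typing import FrozenSet, Iterable, Sequence

import numpy as np

__all__ = [
    "FoodClass",
    "LabelSet",
    "N_CLASSES",
    "labelset",
    "labelset_to_vector",
    "vector_to_labelset",
]


class FoodClass(enum.Enum):
    """One of the ten non-exclusive food-environment retail classes."""

    SPECIALTY_FOODS = "SpecialtyFoods"
    CONVENIENCE = "Convenience"
    FAST_FOOD = "FastFood"
    DISCOUNT = "Discount"
    GROCERY = "Grocery"
    RESTAURANT = "Restaurant"
    ALCOHOL_STORE = "AlcoholStore"
    ALCOHOL_BAR = "AlcoholBar"
    JUICE_COFFEE = "JuiceCoffee"
    SWEETS_DESSERTS = "SweetsDesserts"

    @property
    def display_name(self) -> str:
        return _DISPLAY_NAMES[self]

    @property
    def description(self) -> str:
        return _DESCRIPTIONS[self]

    @property
    def index(self) -> int:
        """Fixed position of this class in label/score vectors."""
        return _ORDER.index(self)

    @classmethod
    def from_name(cls, name: str) -> "FoodClass":
        """Resolve a class from its identifier or display name (case-insensitive)."""
        key = name.strip().lower().replace(" ", "").replace("/", "").replace("_", "")
        for member in cls:
            if key in (
                member.value.lower(),
                member.name.lower().replace("_", ""),
                member.display_name.lower().replace(" ", "").replace("/", ""),
            ):
                return member
        raise ValueError(f"unknown food class name: {name!r}")


_ORDER: tuple = tuple(FoodClass)
N_CLASSES: int = len(_ORDER)
assert N_CLASSES == 10

_DISPLAY_NAMES = {
    FoodClass.SPECIALTY_FOODS: "Specialty Foods",
    FoodClass.CONVENIENCE: "Convenience",
    FoodClass.FAST_FOOD: "Fast Food",
    FoodClass.DISCOUNT: "Discount",
    FoodClass.GROCERY: "Grocery",
    FoodClass.RESTAURANT: "Restaurant",
    FoodClass.ALCOHOL_STORE: "Alcohol Store",
    FoodClass.ALCOHOL_BAR: "Alcohol Bar",
    FoodClass.JUICE_COFFEE: "Juice/Coffee Shops",
    FoodClass.SWEETS_DESSERTS: "Sweets and Desserts",
}

_DESCRIPTIONS = {
    FoodClass.SPECIALTY_FOODS: (
        "Goods stores that predominantly sell a specific type of food such as "
        "cheese, meat, fish or fruit, health food, and international markets."
    ),
    FoodClass.CONVENIENCE: (
        "Smaller goods stores with beverage coolers, lotto/candy, and common "
        "pantry items."
    ),
    FoodClass.FAST_FOOD: (
        "Places preparing standardized food items served or consumed quickly, "
        "including chain fast food and deli counters."
    ),
    FoodClass.DISCOUNT: (
        "Stores selling items at a discount (e.g. 99 cents) that generally do "
        "not sell fresh food."
    ),
    FoodClass.GROCERY: (
        "Goods stores offering a full range of groceries, from corner "
        "groceries to supermarkets."
    ),
    FoodClass.RESTAURANT: (
        "Places preparing food consumed on premises, usually with table "
        "service (sit-down restaurants)."
    ),
    FoodClass.ALCOHOL_STORE: "Goods stores where alcohol is the primary offering.",
    FoodClass.ALCOHOL_BAR: (
        "Locations with bars dedicated to serving alcohol on premises."
    ),
    FoodClass.JUICE_COFFEE: "Stores serving coffee, tea, smoothies, or juice.",
    FoodClass.SWEETS_DESSERTS: (
        "Sweets and dessert stores, including bakeries that also sell desserts."
    ),
}

# A label set is simply a frozen set of FoodClass members; any subset of the
# ten classes is valid, including the empty set (no food label applies).
LabelSet = FrozenSet[FoodClass]


def labelset(*members: FoodClass | str) -> LabelSet:
    """Build a LabelSet from FoodClass members or their names."""
    out = []
    for m in members:
        out.append(m if isinstance(m, FoodClass) else FoodClass.from_name(m))
    return frozenset(out)


def labelset_to_vector(labels: Iterable[FoodClass]) -> np.ndarray:
    """Indicator vector of length 10 in the fixed class order."""
    vec = np.zeros(N_CLASSES, dtype=np.int8)
    for c in labels:
        vec[c.index] = 1
    return vec


def vector_to_labelset(vec: Sequence[float]) -> LabelSet:
    """Inverse of :func:`labelset_to_vector` (nonzero entries are members)."""
    if len(vec) != N_CLASSES:
        raise ValueError(f"label vector must have length {N_CLASSES}, got {len(vec)}")
    return frozenset(c for c in FoodClass if vec[c.index])
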