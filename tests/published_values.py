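"""Published reference values used by the metric and acceptance tests.

Per-class precision/recall/F1 of the production classifier on its hold-out
test set, example raw-score outputs for three store names, and the in-text
band attributions. These are fixed external reference numbers, used only for
internal-consistency checks (harmonic-mean and macro-mean arithmetic,
thresholding, band mapping) — the underlying data is proprietary, so they
are not reproduction targets.
"""

from foodenv.classes import FoodClass

# class -> (precision, recall, f1) on the hold-out test set.
HOLDOUT_METRICS = {
    FoodClass.ALCOHOL_BAR: (0.688, 0.659, 0.673),
    FoodClass.ALCOHOL_STORE: (0.968, 0.928, 0.947),
    FoodClass.CONVENIENCE: (0.762, 0.823, 0.791),
    FoodClass.DISCOUNT: (0.89, 0.807, 0.846),
    FoodClass.FAST_FOOD: (0.757, 0.702, 0.729),
    FoodClass.GROCERY: (0.616, 0.439, 0.513),
    FoodClass.RESTAURANT: (0.618, 0.683, 0.649),
    FoodClass.JUICE_COFFEE: (0.836, 0.419, 0.559),
    FoodClass.SPECIALTY_FOODS: (0.767, 0.558, 0.646),
    FoodClass.SWEETS_DESSERTS: (0.867, 0.643, 0.738),
}

MACRO_F1_PUBLISHED = 0.709
MICRO_F1_PUBLISHED = 0.710

# Rows whose printed F1 equals the harmonic mean of the printed precision and
# recall at 3 dp; the other three differ by <= 1e-3 (rounded inputs).
EXACTLY_CONSISTENT_ROWS = {
    FoodClass.ALCOHOL_BAR,
    FoodClass.CONVENIENCE,
    FoodClass.DISCOUNT,
    FoodClass.GROCERY,
    FoodClass.RESTAURANT,
    FoodClass.SPECIALTY_FOODS,
    FoodClass.SWEETS_DESSERTS,
}

# Example model outputs: name -> class -> (boolean, raw score).
EXAMPLE_OUTPUTS = {
    "Oak and Steel": {
        FoodClass.ALCOHOL_BAR: (True, 0.688),
        FoodClass.ALCOHOL_STORE: (False, 0.406),
        FoodClass.CONVENIENCE: (False, 0.057),
        FoodClass.DISCOUNT: (False, 0.023),
        FoodClass.FAST_FOOD: (False, 0.025),
        FoodClass.GROCERY: (False, 0.018),
        FoodClass.RESTAURANT: (False, 0.411),
        FoodClass.JUICE_COFFEE: (False, 0.075),
        FoodClass.SPECIALTY_FOODS: (False, 0.031),
        FoodClass.SWEETS_DESSERTS: (False, 0.009),
    },
    "La Vina Deli Grocery": {
        FoodClass.ALCOHOL_BAR: (False, 0.006),
        FoodClass.ALCOHOL_STORE: (False, 0.003),
        FoodClass.CONVENIENCE: (True, 0.885),
        FoodClass.DISCOUNT: (False, 0.003),
        FoodClass.FAST_FOOD: (True, 0.942),
        FoodClass.GROCERY: (False, 0.069),
        FoodClass.RESTAURANT: (False, 0.009),
        FoodClass.JUICE_COFFEE: (False, 0.008),
        FoodClass.SPECIALTY_FOODS: (False, 0.038),
        FoodClass.SWEETS_DESSERTS: (False, 0.008),
    },
    "Butcher Bar": {
        FoodClass.ALCOHOL_BAR: (True, 0.797),
        FoodClass.ALCOHOL_STORE: (False, 0.010),
        FoodClass.CONVENIENCE: (False, 0.007),
        FoodClass.DISCOUNT: (False, 0.003),
        FoodClass.FAST_FOOD: (False, 0.019),
        FoodClass.GROCERY: (False, 0.011),
        FoodClass.RESTAURANT: (True, 0.597),
        FoodClass.JUICE_COFFEE: (False, 0.018),
        FoodClass.SPECIALTY_FOODS: (False, 0.041),
        FoodClass.SWEETS_DESSERTS: (False, 0.011),
    },
}

# In-text band attributions.
BAND_ATTRIBUTIONS = [(0.928, "excellent"), (0.439, "fair"), (0.616, "moderate")]
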