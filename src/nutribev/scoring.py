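"""Nutri-Score computation under the 2015 and 2023 beverage algorithms.

The total score is the sum of unfavorable component points (energy, sugars,
saturated fat, sodium/salt, and in 2023 non-nutritive sweeteners) minus the
sum of favorable component points (protein, fiber, FVL percentage). Under the
2015 algorithm, plant-based drinks, milk and milkshakes are scored on the
general-food scale; the 2023 update scores all 12 categories on a single
beverage scale and penalizes non-nutritive sweeteners with 4 points.

Letters run A (best) to E (worst). On the beverage scales A is reserved for
water; every other beverage starts at B regardless of score. The 2015 food
scale assigns A from the score alone and ignores the water flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .products import FOOD_SCALE_2015_CATEGORIES, BeverageProduct
from .scales import AlgorithmScale, PointBandTable, get_scale, theoretical_range

#: Salt (g) = sodium (g) x 2.5; labels declare salt, the 2015 tables use sodium.
SALT_TO_SODIUM_MG: float = 1000.0 / 2.5


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-component points and final score for one product under one version."""

    product_id: str
    version: str
    scale_used: str
    component_points: Mapping[str, int]
    unfavorable_total: int
    favorable_total: int
    total_score: int
    letter: str


def component_points(value: float, table: PointBandTable) -> int:
    """Points for ``value`` under ``table`` (boundary rule: value <= threshold)."""
    return table.lookup(value)


def fvl_points(percent: float, scale: AlgorithmScale) -> int:
    """Points for the fruit/vegetable/legume/qualifying-oil percentage."""
    if not 0 <= percent <= 100:
        raise ValueError(f"fvl_percent must be in [0, 100], got {percent}")
    return scale.tables["fvl"].lookup(percent)


def select_scale_2015(product: BeverageProduct) -> AlgorithmScale:
    """The 2015 algorithm scored plant-based drinks, milk and milkshakes as
    general foods; everything else as a beverage."""
    if product.category in FOOD_SCALE_2015_CATEGORIES:
        return get_scale("food_2015")
    return get_scale("beverage_2015")


def classify(score: int, scale: AlgorithmScale, is_water: bool = False) -> str:
    """Nutri-Score letter for an integer total ``score`` under ``scale``."""
    lo, hi = theoretical_range(scale)
    if not lo <= score <= hi:
        raise ValueError(
            f"score {score} outside theoretical range [{lo}, {hi}] of {scale.name}"
        )
    if scale.water_only_A and is_water:
        return "A"
    for letter, upper in scale.letter_bands:
        if upper is None or score <= upper:
            return letter
    raise AssertionError("unreachable: last letter band is unbounded")


def _score(
    product: BeverageProduct,
    scale: AlgorithmScale,
    values: Mapping[str, float],
    version: str,
    official_protein_rule: bool,
) -> ScoreBreakdown:
    pts = {name: scale.tables[name].lookup(values[name]) for name in scale.tables}
    unfavorable = sum(pts[t.component] for t in scale.unfavorable)
    favorable = sum(pts[t.component] for t in scale.favorable)
    if (
        official_protein_rule
        and version == "v2015"
        and unfavorable >= 11
        and pts["fvl"] < scale.tables["fvl"].max_points
    ):
        # official exception: protein not counted when unfavorable points are
        # high unless the FVL component is at its maximum
        favorable -= pts["protein"]
    total = unfavorable - favorable
    return ScoreBreakdown(
        product_id=product.product_id,
        version=version,
        scale_used=scale.name,
        component_points=pts,
        unfavorable_total=unfavorable,
        favorable_total=favorable,
        total_score=total,
        letter=classify(total, scale, product.is_water),
    )


def score_2015(
    product: BeverageProduct,
    *,
    official_protein_rule: bool = False,
    salt_to_sodium_mg: float = SALT_TO_SODIUM_MG,
) -> ScoreBreakdown:
    """Score one product under the original (2015) algorithm.

    Sodium (mg) is derived from the declared salt as ``salt_g *
    salt_to_sodium_mg``. Missing fiber must already be imputed to 0 by the
    reader. ``official_protein_rule`` opts into the official
    protein-counting exception (withheld by default: the plain
    unfavorable-minus-favorable subtraction is used).
    """
    scale = select_scale_2015(product)
    values = {
        "energy": product.energy_kj,
        "sugars": product.sugars_g,
        "satfat": product.satfat_g,
        "sodium": product.salt_g * salt_to_sodium_mg,
        "protein": product.protein_g,
        "fiber": product.fiber_g or 0.0,
        "fvl": product.fvl_percent,
    }
    return _score(product, scale, values, "v2015", official_protein_rule)


def score_2023(product: BeverageProduct) -> ScoreBreakdown:
    """Score one product under the updated (2023) beverage algorithm.

    All 12 categories use the beverage scale; salt is used directly (g) and
    non-nutritive sweeteners add 4 points when present.
    """
    scale = get_scale("beverage_2023")
    values = {
        "energy": product.energy_kj,
        "sugars": product.sugars_g,
        "satfat": product.satfat_g,
        "salt": product.salt_g,
        "nns": 1.0 if product.has_nns else 0.0,
        "protein": product.protein_g,
        "fiber": product.fiber_g or 0.0,
        "fvl": product.fvl_percent,
    }
    return _score(product, scale, values, "v2023", official_protein_rule=False)


def score_both(
    product: BeverageProduct, *, official_protein_rule: bool = False
) -> tuple[ScoreBreakdown, ScoreBreakdown]:
    """Convenience: (2015 breakdown, 2023 breakdown) for one product."""
    return (
        score_2015(product, official_protein_rule=official_protein_rule),
        score_2023(product),
    )
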