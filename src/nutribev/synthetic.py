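"""Seeded synthetic beverage-market generator.

The study's composition database is not public; only per-category medians and
min-max ranges of the nutrient declaration (per 100 mL) are printed, together
with category sizes. This module emulates those marginals so the whole
scoring/comparison pipeline runs without any download.

Each nutrient is drawn from a two-piece triangular distribution: with
probability 1/2 from the decreasing triangle on [min, median] (mode at the
median), with probability 1/2 from the one on [median, max]. The mixture has
its mode and its median exactly at the published median and support exactly
[min, max] — the minimal assumption honoring all three published numbers.
Sampled energy is then blended 50/50 with the 4/4/9 kcal-per-g Atwater value
from the sampled macronutrients, constrained to ±15 % of the sampled energy
and re-truncated to the published range, so compositions stay physically
plausible. Saturated fat is capped at total fat after sampling.

This is an emulation of published marginals, not of the real joint
distribution: within-product nutrient correlations (beyond the energy and
saturated-fat constraints) and brand structure are not reproduced, so
category-level score medians are indicative, not a reproduction of the
study's values.

One printed inconsistency is resolved at transcription: the legume-based
saturated-fat triplet appears with median 0.3 above max 0.27; the median is
clamped to the max. The legume-based salt triplet (median 0.49, max 2.9
g/100 mL — unusually high for a beverage) is transcribed as printed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .products import KCAL_TO_KJ, BeverageProduct, ProductTable

#: Juice categories get a bimodal FVL mix: pure juices at/above the median
#: versus juice drinks with no qualifying content.
BIMODAL_FVL_CATEGORIES = frozenset({"fruit_juice", "concentrate_nectar", "vegetable_juice"})


@dataclass(frozen=True)
class Triplet:
    """(median, min, max) of one nutrient, per 100 mL."""

    median: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo <= self.median <= self.hi:
            raise ValueError(f"need min <= median <= max, got {self}")


@dataclass(frozen=True)
class CategorySpec:
    """Published marginal distribution of one beverage category.

    ``energy_kcal`` is in kcal/100 mL (as published); products carry kJ.
    """

    category: str
    n_products: int
    energy_kcal: Triplet
    sugars_g: Triplet
    total_fat_g: Triplet
    satfat_g: Triplet
    salt_g: Triplet
    protein_g: Triplet
    fiber_g: Triplet
    fvl_percent: Triplet
    nns_prevalence: float = 0.0
    water_flag_prevalence: float = 0.0
    fvl_bimodal: bool = False
    pure_fvl_weight: float = 0.6

    def __post_init__(self) -> None:
        for p in (self.nns_prevalence, self.water_flag_prevalence, self.pure_fvl_weight):
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of [0,1] in {self.category}: {p}")
        if self.n_products < 0:
            raise ValueError("n_products must be >= 0")


def _t(median, lo, hi) -> Triplet:
    return Triplet(median, lo, hi)


def default_specs() -> list[CategorySpec]:
    """The 12 category specifications, transcribed from the published
    per-category medians and ranges; 3432 products in total."""
    return [
        CategorySpec(
            "alcohol_substitute", 95,
            energy_kcal=_t(22.0, 0.95, 72.0), sugars_g=_t(2.1, 0.0, 18.0),
            total_fat_g=_t(0.0, 0.0, 0.5), satfat_g=_t(0.0, 0.0, 0.1),
            salt_g=_t(0.01, 0.0, 0.3), protein_g=_t(0.1, 0.0, 1.0),
            fiber_g=_t(0.0, 0.0, 3.0), fvl_percent=_t(0.0, 0.0, 24.0),
        ),
        CategorySpec(
            "artificially_sweetened", 288,
            energy_kcal=_t(1.0, 0.0, 16.0), sugars_g=_t(0.0, 0.0, 9.0),
            total_fat_g=_t(0.0, 0.0, 0.9), satfat_g=_t(0.0, 0.0, 0.9),
            salt_g=_t(0.02, 0.0, 0.24), protein_g=_t(0.0, 0.0, 1.5),
            fiber_g=_t(0.0, 0.0, 0.6), fvl_percent=_t(0.0, 0.0, 35.0),
            nns_prevalence=1.0,
        ),
        CategorySpec(
            "sugar_sweetened", 648,
            energy_kcal=_t(33.0, 0.25, 106.0), sugars_g=_t(7.6, 0.0, 16.0),
            total_fat_g=_t(0.0, 0.0, 1.2), satfat_g=_t(0.0, 0.0, 0.5),
            salt_g=_t(0.01, 0.0, 1.0), protein_g=_t(0.0, 0.0, 1.17),
            fiber_g=_t(0.0, 0.0, 0.7), fvl_percent=_t(0.0, 0.0, 100.0),
            nns_prevalence=0.0,
        ),
        CategorySpec(
            "cereal_based", 313,
            energy_kcal=_t(52.0, 22.0, 106.0), sugars_g=_t(6.1, 0.0, 15.2),
            total_fat_g=_t(1.1, 0.0, 12.0), satfat_g=_t(0.2, 0.0, 1.0),
            salt_g=_t(0.09, 0.0, 0.55), protein_g=_t(0.6, 0.0, 3.6),
            fiber_g=_t(0.4, 0.0, 2.7), fvl_percent=_t(0.0, 0.0, 29.0),
        ),
        CategorySpec(
            "legume_based", 165,
            energy_kcal=_t(43.0, 25.0, 79.0), sugars_g=_t(2.9, 0.0, 12.0),
            total_fat_g=_t(1.8, 0.5, 2.9),
            # published median 0.3 exceeds the published max; clamped
            satfat_g=_t(0.27, 0.0, 0.27),
            salt_g=_t(0.49, 0.0, 2.9), protein_g=_t(3.1, 1.5, 5.0),
            fiber_g=_t(0.49, 0.0, 2.9), fvl_percent=_t(11.0, 0.0, 97.4),
        ),
        CategorySpec(
            "nut_based", 123,
            energy_kcal=_t(33.0, 10.42, 85.0), sugars_g=_t(2.5, 0.0, 8.0),
            total_fat_g=_t(1.9, 0.2, 5.0), satfat_g=_t(0.2, 0.0, 0.9),
            salt_g=_t(0.1, 0.0, 0.19), protein_g=_t(0.7, 0.0, 4.2),
            fiber_g=_t(0.3, 0.0, 2.2), fvl_percent=_t(2.8, 0.0, 96.9),
        ),
        CategorySpec(
            "plant_based_mix", 67,
            energy_kcal=_t(60.0, 14.58, 83.0), sugars_g=_t(5.6, 0.0, 9.0),
            total_fat_g=_t(1.5, 0.4, 4.9), satfat_g=_t(0.4, 0.07, 2.6),
            salt_g=_t(0.1, 0.0, 0.3), protein_g=_t(0.5, 0.0, 2.9),
            fiber_g=_t(0.5, 0.1, 1.3), fvl_percent=_t(0.02, 0.0, 15.0),
        ),
        CategorySpec(
            "milk", 148,
            energy_kcal=_t(46.0, 31.0, 70.8), sugars_g=_t(4.7, 4.4, 7.4),
            total_fat_g=_t(1.6, 0.0, 3.7), satfat_g=_t(1.05, 0.0, 2.5),
            salt_g=_t(0.13, 0.1, 0.2), protein_g=_t(3.1, 3.0, 5.4),
            fiber_g=_t(0.0, 0.0, 0.0), fvl_percent=_t(0.0, 0.0, 0.0),
        ),
        CategorySpec(
            "milkshake", 139,
            energy_kcal=_t(45.0, 11.0, 88.0), sugars_g=_t(7.5, 1.9, 13.0),
            total_fat_g=_t(0.1, 0.0, 2.8), satfat_g=_t(0.0, 0.0, 1.8),
            salt_g=_t(0.1, 0.0, 0.25), protein_g=_t(0.5, 0.0, 8.3),
            fiber_g=_t(0.0, 0.0, 1.2), fvl_percent=_t(3.2, 0.0, 90.0),
        ),
        CategorySpec(
            "fruit_juice", 193,
            energy_kcal=_t(48.0, 12.0, 91.0), sugars_g=_t(9.2, 0.0, 15.0),
            total_fat_g=_t(0.2, 0.0, 6.0), satfat_g=_t(0.03, 0.0, 4.7),
            salt_g=_t(0.02, 0.0, 7.0), protein_g=_t(0.5, 0.0, 2.6),
            fiber_g=_t(0.0, 0.0, 11.0), fvl_percent=_t(99.0, 0.0, 100.0),
            fvl_bimodal=True,
        ),
        CategorySpec(
            "concentrate_nectar", 916,
            energy_kcal=_t(45.0, 4.0, 95.0), sugars_g=_t(9.9, 0.0, 23.0),
            total_fat_g=_t(0.1, 0.0, 2.0), satfat_g=_t(0.0, 0.0, 1.5),
            salt_g=_t(0.01, 0.0, 0.4), protein_g=_t(0.3, 0.0, 2.9),
            fiber_g=_t(0.0, 0.0, 2.5), fvl_percent=_t(99.0, 0.0, 100.0),
            fvl_bimodal=True,
        ),
        CategorySpec(
            "vegetable_juice", 337,
            energy_kcal=_t(40.0, 2.4, 186.0), sugars_g=_t(4.1, 0.0, 19.0),
            total_fat_g=_t(0.1, 0.0, 14.0), satfat_g=_t(0.0, 0.0, 2.2),
            salt_g=_t(0.05, 0.0, 2.0), protein_g=_t(0.6, 0.0, 3.5),
            fiber_g=_t(0.0, 0.0, 3.4), fvl_percent=_t(54.0, 0.0, 100.0),
            fvl_bimodal=True,
        ),
    ]


def load_specs(path) -> list[CategorySpec]:
    """Load category specs from a JSON file overriding the defaults.

    The file maps category -> {field: value} with triplets as
    ``[median, min, max]`` lists; unlisted categories keep their defaults.
    """
    with open(path, encoding="utf-8") as fh:
        overrides = json.load(fh)
    specs = []
    for spec in default_specs():
        ov = overrides.get(spec.category)
        if ov:
            kwargs = {
                k: Triplet(*v) if isinstance(v, (list, tuple)) else v
                for k, v in ov.items()
            }
            spec = replace(spec, **kwargs)
        specs.append(spec)
    return specs


def _two_piece(rng: np.random.Generator, t: Triplet, n: int) -> np.ndarray:
    """Two-piece triangular: mode and median both at t.median, support [lo, hi]."""
    out = np.full(n, t.median, dtype=float)
    right = rng.random(n) < 0.5
    if t.hi > t.median:
        k = int(right.sum())
        out[right] = rng.triangular(t.median, t.median, t.hi, size=k)
    if t.median > t.lo:
        k = int((~right).sum())
        out[~right] = rng.triangular(t.lo, t.median, t.median, size=k)
    return out


def sample_category(
    spec: CategorySpec, n: Optional[int] = None, seed=0
) -> list[BeverageProduct]:
    """Draw ``n`` products (default ``spec.n_products``) from one category.

    ``seed`` may be an int or a ``numpy.random.Generator``. Values are
    rounded to 2 decimals (label face precision); all draws stay within the
    published [min, max] bounds.
    """
    if n is None:
        n = spec.n_products
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    sugars = _two_piece(rng, spec.sugars_g, n)
    fat = _two_piece(rng, spec.total_fat_g, n)
    satfat = np.minimum(_two_piece(rng, spec.satfat_g, n), fat)
    salt = _two_piece(rng, spec.salt_g, n)
    protein = _two_piece(rng, spec.protein_g, n)
    fiber = _two_piece(rng, spec.fiber_g, n)

    if spec.fvl_bimodal:
        pure = rng.random(n) < spec.pure_fvl_weight
        upper = Triplet(spec.fvl_percent.median, spec.fvl_percent.median, spec.fvl_percent.hi)
        fvl = np.where(pure, _two_piece(rng, upper, n), 0.0)
    else:
        fvl = _two_piece(rng, spec.fvl_percent, n)

    kcal = _two_piece(rng, spec.energy_kcal, n)
    kcal_atwater = 4.0 * (sugars + protein) + 9.0 * fat + 2.0 * fiber
    blended = 0.5 * kcal + 0.5 * kcal_atwater
    kcal_final = np.clip(blended, 0.85 * kcal, 1.15 * kcal)
    kcal_final = np.clip(kcal_final, spec.energy_kcal.lo, spec.energy_kcal.hi)

    has_nns = rng.random(n) < spec.nns_prevalence
    is_water = rng.random(n) < spec.water_flag_prevalence

    products = []
    for i in range(n):
        products.append(
            BeverageProduct(
                product_id=f"{spec.category}-{i:05d}",
                category=spec.category,
                energy_kj=round(float(kcal_final[i]) * KCAL_TO_KJ, 2),
                sugars_g=round(float(sugars[i]), 2),
                total_fat_g=round(float(fat[i]), 2),
                satfat_g=round(float(min(satfat[i], fat[i])), 2),
                salt_g=round(float(salt[i]), 2),
                protein_g=round(float(protein[i]), 2),
                fiber_g=round(float(fiber[i]), 2),
                fvl_percent=round(float(fvl[i]), 2),
                has_nns=bool(has_nns[i]),
                is_water=bool(is_water[i]),
            )
        )
    return products


def generate_market(
    seed: int = 0,
    scale: float = 1.0,
    specs: Optional[Sequence[CategorySpec]] = None,
) -> ProductTable:
    """Generate a full synthetic market (default 3432 products).

    ``scale`` shrinks every category proportionally (minimum 1 product per
    category) for fast runs. Deterministic for a fixed (seed, scale, specs).
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    if specs is None:
        specs = default_specs()
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(specs))
    rows: list[BeverageProduct] = []
    for spec, child in zip(specs, children):
        n = max(1, round(spec.n_products * scale))
        rng = np.random.default_rng(child)
        rows.extend(sample_category(spec, n=n, seed=rng))
    return ProductTable(
        rows=rows,
        provenance=f"synthetic market (seed={seed}, scale={scale})",
    )
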