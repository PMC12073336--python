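"""Beverage product records and their validation rules.

A :class:`BeverageProduct` is one labeled product's nutrient declaration per
100 mL, its ingredient-derived attributes (fruit/vegetable/legume/qualifying-oil
percentage, non-nutritive-sweetener presence, water flag) and its market
category. All nutrient fields are non-negative; saturated fat can never exceed
total fat; fiber may be missing (``None``) until the reader imputes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

#: The 12 beverage market categories.
CATEGORIES: tuple[str, ...] = (
    "alcohol_substitute",
    "artificially_sweetened",
    "sugar_sweetened",
    "cereal_based",
    "legume_based",
    "nut_based",
    "plant_based_mix",
    "milk",
    "milkshake",
    "fruit_juice",
    "concentrate_nectar",
    "vegetable_juice",
)

#: Categories that the original (2015) algorithm scored on the general-food
#: scale rather than the beverage scale: plant-based drinks, milk, milkshakes.
FOOD_SCALE_2015_CATEGORIES: frozenset[str] = frozenset(
    {
        "cereal_based",
        "legume_based",
        "nut_based",
        "plant_based_mix",
        "milk",
        "milkshake",
    }
)

#: kcal -> kJ conversion factor (EU labeling convention).
KCAL_TO_KJ: float = 4.184


class BeverageProduct(BaseModel):
    """One beverage's composition per 100 mL plus ingredient flags.

    Parameters
    ----------
    product_id : str
        Opaque unique identifier.
    category : str
        One of :data:`CATEGORIES`.
    energy_kj : float
        Energy in kJ per 100 mL.
    sugars_g, total_fat_g, satfat_g, salt_g, protein_g : float
        Nutrient declaration in g per 100 mL (salt as salt, not sodium).
    fiber_g : float or None
        Fiber in g per 100 mL; ``None`` means not declared (imputed to 0 by
        the reader, which counts imputations).
    fvl_percent : float
        Percentage (0-100) of fruits, vegetables, legumes and qualifying oils
        (nut, canola/rapeseed, walnut, olive).
    has_nns : bool
        Non-nutritive sweeteners present in the ingredient list.
    is_water : bool
        Plain/mineral water (the only products eligible for letter A on the
        beverage scales).
    """

    model_config = ConfigDict(frozen=True)

    product_id: str
    category: str
    energy_kj: float = Field(ge=0)
    sugars_g: float = Field(ge=0)
    total_fat_g: float = Field(ge=0)
    satfat_g: float = Field(ge=0)
    salt_g: float = Field(ge=0)
    protein_g: float = Field(ge=0)
    fiber_g: Optional[float] = Field(default=None, ge=0)
    fvl_percent: float = Field(default=0.0, ge=0, le=100)
    has_nns: bool = False
    is_water: bool = False

    @model_validator(mode="after")
    def _check_consistency(self) -> "BeverageProduct":
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )
        if self.satfat_g > self.total_fat_g + 1e-9:
            raise ValueError(
                f"saturated fat ({self.satfat_g} g) exceeds total fat "
                f"({self.total_fat_g} g)"
            )
        return self


@dataclass
class ProductTable:
    """A validated collection of products plus read-time bookkeeping."""

    rows: list[BeverageProduct]
    provenance: str = ""
    fiber_imputed_count: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.product_id for p in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate product_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame([p.model_dump() for p in self.rows])
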