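"""Point-band tables and algorithm scales.

The Nutri-Score nutrient-profiling model awards integer points per component
from an ordered list of thresholds. Each band is a pair
``(upper_threshold, points)`` with the boundary convention ``value <=
threshold`` earns that band's points; a value strictly above the last
threshold earns ``top_points``. Three scales are shipped as versioned JSON
configuration:

``beverage_2015``
    the original beverage algorithm (sodium-based, FVL up to 10 points);
``food_2015``
    the original general-food algorithm, applied in 2015 to plant-based
    drinks, milk and milkshakes;
``beverage_2023``
    the updated beverage algorithm (salt-based, non-nutritive-sweetener
    penalty, FVL up to 6 points), applied to all 12 categories.

Only the endpoint spans of each component are fixed by the published
description of the update; the interior thresholds are the official
Santé Publique France tables.
"""

from __future__ import annotations

import json
from bisect import bisect_left
from functools import lru_cache
from importlib import resources
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, model_validator

Component = Literal[
    "energy", "sugars", "satfat", "sodium", "salt", "nns", "protein", "fiber", "fvl"
]

SCALE_NAMES = ("beverage_2015", "food_2015", "beverage_2023")


class PointBandTable(BaseModel):
    """Ordered threshold -> points map for one component under one scale."""

    model_config = ConfigDict(frozen=True)

    component: Component
    polarity: Literal["favorable", "unfavorable"]
    unit: str = ""
    bands: tuple[tuple[float, int], ...]
    top_points: int

    @model_validator(mode="after")
    def _check_bands(self) -> "PointBandTable":
        if not self.bands:
            raise ValueError(f"{self.component}: empty band list")
        thresholds = [t for t, _ in self.bands]
        if any(b >= a for a, b in zip(thresholds[1:], thresholds)):
            raise ValueError(f"{self.component}: thresholds must be strictly increasing")
        points = [p for _, p in self.bands] + [self.top_points]
        if any(b > a for a, b in zip(points[1:], points)):
            raise ValueError(f"{self.component}: points must be non-decreasing")
        return self

    @property
    def max_points(self) -> int:
        return self.top_points

    @property
    def min_points(self) -> int:
        return self.bands[0][1]

    def lookup(self, value: float) -> int:
        """Points for ``value``: first band whose threshold >= value, else top."""
        if value < 0:
            raise ValueError(f"{self.component}: negative value {value}")
        thresholds = [t for t, _ in self.bands]
        i = bisect_left(thresholds, value)
        if i < len(self.bands):
            return self.bands[i][1]
        return self.top_points


class AlgorithmScale(BaseModel):
    """One scoring scale: its band tables and letter cut-offs.

    ``letter_bands`` lists ``(letter, upper_score)`` pairs in increasing
    order, the last with ``upper_score = None`` (unbounded). Beverage scales
    have ``water_only_A = True``: letter A is reserved for water and the
    letter bands start at B.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    version: Literal["v2015", "v2023"]
    water_only_A: bool
    letter_bands: tuple[tuple[str, Optional[int]], ...]
    tables: dict[str, PointBandTable]

    @model_validator(mode="after")
    def _check(self) -> "AlgorithmScale":
        uppers = [u for _, u in self.letter_bands[:-1]]
        if self.letter_bands[-1][1] is not None:
            raise ValueError("last letter band must be unbounded")
        if any(b <= a for a, b in zip(uppers, uppers[1:])):
            raise ValueError("letter cut-offs must be strictly increasing")
        if self.water_only_A and self.letter_bands[0][0] == "A":
            raise ValueError("water-only scales must not define a scored A band")
        return self

    @property
    def favorable(self) -> list[PointBandTable]:
        return [t for t in self.tables.values() if t.polarity == "favorable"]

    @property
    def unfavorable(self) -> list[PointBandTable]:
        return [t for t in self.tables.values() if t.polarity == "unfavorable"]


def _scale_from_dict(doc: dict) -> AlgorithmScale:
    tables = {
        name: PointBandTable(
            component=name,
            polarity=spec["polarity"],
            unit=spec.get("unit", ""),
            bands=tuple((float(t), int(p)) for t, p in spec["bands"]),
            top_points=int(spec["top_points"]),
        )
        for name, spec in doc["components"].items()
    }
    return AlgorithmScale(
        name=doc["name"],
        version=doc["version"],
        water_only_A=doc["water_only_A"],
        letter_bands=tuple(
            (letter, None if upper is None else int(upper))
            for letter, upper in doc["letter_bands"]
        ),
        tables=tables,
    )


def load_scale(source) -> AlgorithmScale:
    """Load and validate an :class:`AlgorithmScale` from a JSON file or dict."""
    if isinstance(source, dict):
        return _scale_from_dict(source)
    with open(source, encoding="utf-8") as fh:
        return _scale_from_dict(json.load(fh))


@lru_cache(maxsize=None)
def get_scale(name: str) -> AlgorithmScale:
    """Return one of the shipped scales (:data:`SCALE_NAMES`)."""
    if name not in SCALE_NAMES:
        raise ValueError(f"unknown scale {name!r}; expected one of {SCALE_NAMES}")
    text = resources.files("nutribev.data").joinpath(f"{name}.json").read_text("utf-8")
    return _scale_from_dict(json.loads(text))


def theoretical_range(scale: AlgorithmScale) -> tuple[int, int]:
    """(min, max) achievable total: -sum of favorable maxima, +sum of
    unfavorable maxima."""
    lo = -sum(t.max_points for t in scale.favorable)
    hi = sum(t.max_points for t in scale.unfavorable)
    return lo, hi
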