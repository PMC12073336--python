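"""Scoring under both algorithm versions: worked examples, the letter
assignment, monotonicity and the band-lookup oracle."""

import dataclasses

import numpy as np
import pytest

from nutribev import (
    classify,
    component_points,
    fvl_points,
    get_scale,
    score_2015,
    score_2023,
    select_scale_2015,
    theoretical_range,
)
from nutribev.products import BeverageProduct

from conftest import make_product


class TestFvlPoints:
    """The fruit/vegetable/legume step function, exactly as published."""

    @pytest.mark.parametrize(
        "percent,scale,expected",
        [
            (40, "beverage_2015", 0),
            (41, "beverage_2015", 2),
            (61, "beverage_2015", 4),
            (81, "beverage_2015", 10),
            (81, "food_2015", 5),
            (41, "food_2015", 1),
            (61, "food_2015", 2),
            (40, "beverage_2023", 0),
            (41, "beverage_2023", 2),
            (61, "beverage_2023", 4),
            (81, "beverage_2023", 6),
            (100, "beverage_2023", 6),
        ],
    )
    def test_steps(self, percent, scale, expected):
        assert fvl_points(percent, get_scale(scale)) == expected

    @pytest.mark.parametrize("percent", [-1, 100.5])
    def test_out_of_range(self, percent):
        with pytest.raises(ValueError):
            fvl_points(percent, get_scale("beverage_2015"))


class TestScaleSelection:
    @pytest.mark.parametrize(
        "category",
        ["cereal_based", "legume_based", "nut_based", "plant_based_mix", "milk", "milkshake"],
    )
    def test_food_scale_categories(self, category):
        assert select_scale_2015(make_product(category=category)).name == "food_2015"

    @pytest.mark.parametrize(
        "category",
        ["sugar_sweetened", "fruit_juice", "artificially_sweetened",
         "alcohol_substitute", "concentrate_nectar", "vegetable_juice"],
    )
    def test_beverage_scale_categories(self, category):
        assert select_scale_2015(make_product(category=category)).name == "beverage_2015"

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="category"):
            make_product(category="smoothie")


class TestScore2015:
    def test_zero_composition(self):
        b = score_2015(make_product())
        assert (b.unfavorable_total, b.favorable_total, b.total_score) == (0, 0, 0)
        assert b.letter == "B"

    def test_top_sugar_and_energy(self):
        # above the published top thresholds (>13.5 g, >270 kJ) on the
        # beverage scale: 10 + 10 points
        b = score_2015(make_product(sugars_g=14.0, energy_kj=280.0))
        assert b.component_points["sugars"] == 10
        assert b.component_points["energy"] == 10
        assert b.total_score == 20
        assert b.letter == "E"

    def test_sweetener_has_no_effect(self):
        plain = score_2015(make_product(sugars_g=5, energy_kj=120))
        sweet = score_2015(make_product(sugars_g=5, energy_kj=120, has_nns=True))
        assert plain.total_score == sweet.total_score
        assert plain.component_points == sweet.component_points

    def test_sodium_derived_from_salt(self):
        # 1 g salt = 400 mg sodium -> 4 points on the 90 mg-step table
        b = score_2015(make_product(salt_g=1.0))
        assert b.component_points["sodium"] == 4

    def test_official_protein_rule_withholds_protein(self):
        p = make_product(sugars_g=14, energy_kj=280, protein_g=9.0)
        plain = score_2015(p)
        official = score_2015(p, official_protein_rule=True)
        assert plain.total_score == 20 - 5
        assert official.total_score == 20  # unfavorable 20 >= 11, FVL not maximal
        maxed = make_product(sugars_g=14, energy_kj=280, protein_g=9.0, fvl_percent=90)
        assert score_2015(maxed, official_protein_rule=True).total_score == 20 - 5 - 10


class TestScore2023:
    def test_sweetener_penalty_alone(self):
        assert score_2023(make_product(has_nns=True)).total_score == 4
        assert score_2023(make_product(has_nns=False)).total_score == 0

    def test_protein_above_top_threshold(self):
        b = score_2023(make_product(protein_g=3.5))
        assert b.total_score == -7
        assert b.letter == "B"

    def test_all_categories_use_beverage_scale(self):
        for category in ("milk", "milkshake", "cereal_based", "sugar_sweetened"):
            assert score_2023(make_product(category=category)).scale_used == "beverage_2023"

    def test_salt_scored_directly(self):
        assert score_2023(make_product(salt_g=5.0)).component_points["salt"] == 20


class TestClassify:
    @pytest.mark.parametrize(
        "score,scale,is_water,letter",
        [
            (11, "beverage_2015", False, "E"),
            (1, "beverage_2015", False, "B"),
            (2, "beverage_2015", False, "C"),
            (5, "beverage_2015", False, "C"),
            (6, "beverage_2015", False, "D"),
            (9, "beverage_2015", False, "D"),
            (10, "beverage_2015", False, "E"),
            (-20, "beverage_2015", False, "B"),
            (2, "beverage_2023", False, "B"),
            (3, "beverage_2023", False, "C"),
            (6, "beverage_2023", False, "C"),
            (7, "beverage_2023", False, "D"),
            (10, "beverage_2023", False, "E"),
            (0, "beverage_2023", True, "A"),
            (-1, "food_2015", False, "A"),
            (0, "food_2015", False, "B"),
            (6, "food_2015", False, "C"),
            (19, "food_2015", False, "E"),
        ],
    )
    def test_letter_bands(self, score, scale, is_water, letter):
        assert classify(score, get_scale(scale), is_water) == letter

    def test_food_scale_ignores_water_flag(self):
        assert classify(6, get_scale("food_2015"), is_water=True) == "C"

    @pytest.mark.parametrize("scale,score", [("beverage_2015", 41), ("beverage_2023", -19)])
    def test_out_of_range_rejected(self, scale, score):
        with pytest.raises(ValueError, match="theoretical range"):
            classify(score, get_scale(scale))

    @pytest.mark.parametrize("scale", ["beverage_2015", "beverage_2023", "food_2015"])
    def test_total_and_exclusive_over_range(self, scale):
        """classify is defined for every integer score in the theoretical
        range and partitions it into contiguous letter bands."""
        sc = get_scale(scale)
        lo, hi = theoretical_range(sc)
        letters = [classify(s, sc, False) for s in range(lo, hi + 1)]
        assert all(a <= b for a, b in zip(letters, letters[1:]))  # monotone A..E
        expected_first = "A" if not sc.water_only_A else sc.letter_bands[0][0]
        assert letters[0] == expected_first
        assert letters[-1] == "E"


class TestBandLookupOracle:
    """component_points agrees with an exhaustive linear scan of the bands."""

    @staticmethod
    def _linear_scan(value, table):
        for threshold, points in table.bands:
            if value <= threshold:
                return points
        return table.top_points

    @pytest.mark.parametrize("scale", ["beverage_2015", "food_2015", "beverage_2023"])
    def test_oracle_equivalence(self, scale):
        rng = np.random.default_rng(42)
        for table in get_scale(scale).tables.values():
            top = table.bands[-1][0]
            values = rng.uniform(0, top * 1.5 if top > 0 else 10.0, size=10_000)
            # hit band boundaries exactly as well
            values = np.concatenate([values, [t for t, _ in table.bands]])
            for v in values:
                assert component_points(v, table) == self._linear_scan(v, table)


class TestBandProperties:
    """Band lookup is monotone and bounded for arbitrary non-negative values."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(value=st.floats(min_value=0, max_value=1e4, allow_nan=False))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_lookup_bounded_and_monotone(self, value):
        for scale in ("beverage_2015", "food_2015", "beverage_2023"):
            for table in get_scale(scale).tables.values():
                pts = component_points(value, table)
                assert table.min_points <= pts <= table.max_points
                assert component_points(value + 1.0, table) >= pts


class TestInvariants:
    UNFAVORABLE = ["sugars_g", "energy_kj", "satfat_g", "salt_g"]
    FAVORABLE = ["protein_g", "fiber_g", "fvl_percent"]

    @pytest.mark.parametrize("scorer", [score_2015, score_2023])
    @pytest.mark.parametrize("fld", UNFAVORABLE + FAVORABLE)
    def test_monotonicity(self, scorer, fld):
        hi = 100 if fld == "fvl_percent" else (500 if fld == "energy_kj" else 12)
        sweep = np.linspace(0, hi, 60)
        extra = {"total_fat_g": 12.0} if fld == "satfat_g" else {}
        totals = [scorer(make_product(**{fld: v}, **extra)).total_score for v in sweep]
        diffs = np.diff(totals)
        if fld in self.UNFAVORABLE:
            assert (diffs >= 0).all()
        else:
            assert (diffs <= 0).all()

    def test_sweetener_delta_exactly_four(self, small_market):
        for p in small_market:
            on = p.model_copy(update={"has_nns": True})
            off = p.model_copy(update={"has_nns": False})
            assert score_2023(on).total_score - score_2023(off).total_score == 4
            assert score_2015(on).total_score == score_2015(off).total_score

    def test_scores_within_theoretical_range(self, small_market):
        for p in small_market:
            for b in (score_2015(p), score_2023(p)):
                lo, hi = theoretical_range(get_scale(b.scale_used))
                assert lo <= b.total_score <= hi

    def test_determinism_identical_rows(self):
        p = make_product(sugars_g=7.3, energy_kj=150, protein_g=2.0, fiber_g=1.1)
        q = BeverageProduct(**p.model_dump())
        b1, b2 = score_2023(p), score_2023(q)
        assert dataclasses.asdict(b1) == dataclasses.asdict(b2)
        assert dataclasses.asdict(score_2015(p)) == dataclasses.asdict(score_2015(q))
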