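# nutribev

Nutri-Score nutrient profiling for beverages: the original (2015) and
updated (2023) scoring algorithms, a seeded synthetic beverage-market
generator, and a paired comparison of how the two algorithm versions
classify the same products.

## Who this is for

Nutrition and public-health researchers studying front-of-pack labeling.
The Nutri-Score label assigns each product a letter A (dark green, best) to
E (red, worst) from a points-based nutrient profiling model (NS-NPM). The
model was revised for beverages in 2023, changing point bands, reclassifying
plant-based drinks, milk and milkshakes from foods to beverages, and adding
a penalty for non-nutritive sweeteners. This package scores per-100 mL
beverage composition tables under both versions and quantifies how the
revision moves scores, letters and category discrimination.

## The model

For a product with composition per 100 mL, each component is mapped to
integer points through an ordered band table (value ≤ threshold earns that
band's points; above the last threshold earns the maximum). The total is

```
S = Σ unfavorable points − Σ favorable points
```

| scale | unfavorable (max) | favorable (max) | range |
|---|---|---|---|
| 2015 beverages | energy 10, sugars 10, sat. fat 10, sodium 10 | protein 5, fiber 5, FVL 10 | −20 … 40 |
| 2015 foods (plant-based drinks, milk, milkshakes) | energy 10, sugars 10, sat. fat 10, sodium 10 | protein 5, fiber 5, FVL 5 | −15 … 40 |
| 2023 beverages (all categories) | energy 10, sugars 10, sat. fat 10, salt 20, sweeteners 4 | protein 7, fiber 5, FVL 6 | −18 … 54 |

FVL is the declared percentage of fruits, vegetables, legumes and
qualifying oils (nut, rapeseed, walnut, olive). Letters for beverages:
A is reserved for water; 2015 cut-offs B ≤ 1, C 2–5, D 6–9, E ≥ 10;
2023 cut-offs B ≤ 2, C 3–6, D 7–9, E ≥ 10. The 2015 food scale uses the
food cut-offs (A ≤ −1, B 0–2, C 3–10, D 11–18, E ≥ 19).

The comparison stage pairs every product's two scores and reports, per
category: medians and ranges, relative variation
`((S₂₀₂₃ − S₂₀₁₅)/S₂₀₁₅) × 100`, a Wilcoxon signed-rank test (exact and
tie-aware for ≤ 25 nonzero pairs), Spearman rank consistency, modal
letters, Cohen's kappa agreement between letter assignments, a chi-square
on the letter distributions, and the number of distinct letters (the
label's discriminatory "color count").

## Worked example

```python
import nutribev as nb

cola = nb.BeverageProduct(
    product_id="cola-01", category="sugar_sweetened",
    energy_kj=180, sugars_g=10.6, total_fat_g=0, satfat_g=0,
    salt_g=0.02, protein_g=0, fiber_g=0, fvl_percent=0, has_nns=False,
)
b15, b23 = nb.score_both(cola)
print(b15.total_score, b15.letter)   # 14 E   (energy 6 + sugars 8)
print(b23.total_score, b23.letter)   # 12 E   (energy 3 + sugars 9)
```

The same cola loses two points under the update (energy bands are more
lenient below 390 kJ, sugar bands stricter) but stays an E. Market-level
comparison on a synthetic batch:

```python
market = nb.generate_market(seed=1, scale=0.1)   # 344 products, 12 categories
res = nb.NutriScoreComparison(market).fit()
print(res.summary())
```

```
Nutri-Score 2015 vs 2023 paired comparison
==============================================================================
products: 344    categories: 12
overall kappa: 0.288    overall chi2: 46.08 (df=4, p=2.37e-09)
------------------------------------------------------------------------------
              category  n  med15  med23  relvar%  p(W)  rho L15 L23  kappa%
    alcohol_substitute 10   6.00   4.00   -35.20  0.00 0.84   D   C   -2.56
artificially_sweetened 29   2.00   5.00   160.29  0.00 0.96   C   C  -16.49
          cereal_based 31   1.00   9.00   498.08  0.00 0.60   B   E   -8.47
...
```

Read: the median cereal-based drink jumps from 1 to 9 points (B toward
D/E) because the update scores it as a beverage; artificially sweetened
drinks rise by the 4-point sweetener penalty; letter agreement (kappa) is
low wherever cut-offs moved across a category's score mass. The synthetic
market emulates published per-category medians and ranges, so these
numbers illustrate the mechanics rather than reproduce any proprietary
database.

The same pipeline from a shell:

```sh
nutribev simulate --seed 1 --scale 0.1 --out products.csv
nutribev score --in products.csv --out scores.csv
nutribev compare --in scores.csv --out-dir results/
```

`score` accepts any CSV with the documented columns (`product_id,
category, energy_kj and/or energy_kcal, sugars_g, total_fat_g, satfat_g,
salt_g, protein_g, fiber_g, fvl_percent, has_nns, is_water,
ingredients_text`); kcal is converted when kJ is absent, blank fiber is
imputed to 0 and counted, sweetener presence can be derived from the
ingredient text, and invalid rows are rejected with line numbers.

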