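# Methods

## Scoring model

Both algorithm versions are rule-based point systems over a product's
composition per 100 mL. Each component value passes through an ordered
band table `(upper_threshold, points)` with the boundary convention
*value ≤ threshold earns that band's points*; a value strictly above the
last threshold earns the component maximum. This convention matches every
published step description (e.g. FVL "0 points for ≤ 40 %, 2 points for
> 40 %"). The total score is the unfavorable sum minus the favorable sum;
no intermediate rounding is applied, and label values are taken at face
precision.

Published descriptions of the algorithms fix each component's endpoint
span (first threshold, maximum points) but not the interior thresholds.
The shipped JSON tables (`src/nutribev/data/*.json`) are the official
Santé Publique France band tables; the unit tests pin the published
endpoints and point-range widths, which are the externally verifiable
anchors. For 2015 fiber the published endpoints (≤ 0.7 to > 3.5 g)
identify the NSP fiber table, which is the variant shipped.

Decisions taken where the published description is silent or ambiguous:

- **Sodium vs salt (2015).** Labels declare salt (g); the 2015 tables are
  sodium-based (mg). Internally `sodium_mg = salt_g × 1000 / 2.5`
  (configurable factor).
- **Saturated fat in 2023.** The update's component list does not restate
  saturated fat, but the published −18…54 range requires it
  (10 + 10 + 10 + 20 + 4 = 54); the 0–10 component is retained.
- **Letter B lower bound.** Since A is water-only on the beverage scales,
  B covers all scores at or below its cut-off (≤ 1 in 2015, ≤ 2 in 2023).
- **2015 food-scale letters.** Plant-based drinks, milk and milkshakes are
  classified with the official 2015 food cut-offs (A ≤ −1, B 0–2, C 3–10,
  D 11–18, E ≥ 19), which reproduce the published food-scale
  median-to-letter pairs (−1 → A, 0 → B, 6 → C). The food scale ignores
  the water flag.
- **Protein-counting exception.** The official 2015 algorithm withholds
  protein points when unfavorable points reach 11 unless the FVL component
  is at its maximum. The published computation description states the plain
  subtraction, so the plain rule is the default and the official exception
  is opt-in (`official_protein_rule=True`, applied to 2015 only; no 2023
  beverage protein exception is documented, and none is applied).

`classify` validates that a score lies inside the scale's theoretical
range (sum of component extrema) and is total and exclusive over it.

## Synthetic market generator

Only per-category marginals are published for the underlying beverage
database: median and [min; max] of each nutrient, plus category sizes
(3432 products over 12 categories). The generator emulates exactly those
numbers:

- **Distribution family.** Each nutrient is a 50/50 two-piece triangular
  mixture: a decreasing triangle on [min, median] and one on [median, max],
  both with mode at the median. The mixture's support, mode and median are
  exactly the three published numbers — the minimal assumption honoring
  all of them. Degenerate pieces (median = min or = max) collapse to point
  mass, which conveniently reproduces the large observed spikes at zero.
- **Energy coherence.** Sampled energy (kcal) is blended 50/50 with the
  Atwater value 4·(sugars + protein) + 9·fat + 2·fiber from the sampled
  macronutrients, constrained to ±15 % of the sampled energy and
  re-truncated to the published range, so no physically impossible rows
  reach the scorer. This pulls the energy median slightly off the
  published value; all other nutrients match their medians as n grows.
- **Constraints.** Saturated fat is capped at total fat after sampling.
  Values are rounded to 2 decimals (label face precision); all draws stay
  within the published bounds.
- **FVL bimodality.** Juice categories (fruit juice, concentrates/nectars,
  vegetable juice) mix pure juices (weight 0.6, triangular from the median
  up) with zero-content drinks (weight 0.4), mimicking markets of pure
  juices and juice drinks while keeping the published median.
- **Sweetener prevalence.** 1.0 in the artificially sweetened category,
  0.0 elsewhere (the published categorization assigns sweetener-containing
  products to that category). No category has the water flag: mineral
  water was outside the published sample.
- **Transcription note.** The published legume-based saturated-fat triplet
  (median 0.3, max 0.27) is internally inconsistent; the median is clamped
  to the max. The legume-based salt triplet (median 0.49, max 2.9 g/100 mL)
  is unusually high for a beverage but transcribed as printed.
- **Determinism.** One root `SeedSequence` spawns a child stream per
  category, so any (seed, scale) pair gives byte-identical output across
  runs and platforms; `scale` shrinks category sizes proportionally
  (minimum 1) for fast runs.

What the emulation does *not* capture: within-product correlations beyond
the energy/saturated-fat constraints, brand structure, and the real joint
distribution. Passing tests therefore demonstrate the scoring and
comparison machinery on realistic marginals, not agreement with the
original database's category medians, p-values or agreement statistics —
which are explicitly out of reach without the raw rows.

## Comparison statistics

- **Relative variation** per product is ((S₂₀₂₃ − S₂₀₁₅)/S₂₀₁₅) × 100,
  undefined when S₂₀₁₅ = 0. Three aggregations are selectable:
  `exclude-zeros` (default; mean over defined values, excluded count
  reported), `pratt-style` (keep zero-denominator products by substituting
  a 1-point denominator — a package convention, named for its
  keep-the-zeros spirit), and `median-of` (variation of the category
  medians). The default is the most literal reading of the per-product
  formula.
- **Wilcoxon signed-rank**, two-sided. Zero differences are dropped
  (Wilcoxon's convention; Pratt's ranking available via
  `zero_method="pratt"`). Tied absolute differences are mid-ranked. With
  n ≤ 25 nonzero pairs the p-value is exact even under ties, computed by a
  dynamic program over doubled mid-ranks (the distribution of W⁺ over all
  2ⁿ sign assignments); above that, a normal approximation with tie
  correction (Var W⁺ = Σrᵢ²/4) and a 0.5 continuity correction. The two
  branches agree within 0.01 at the handover size on random integer-score
  fixtures.
- **Spearman rho** is the product-moment correlation of mid-ranks
  (`scipy.stats.spearmanr`); zero variance in either margin is flagged
  undefined rather than returned as a number.
- **Kappa.** Unweighted Cohen's kappa on the 5-letter scale by default;
  linear weights optional since letters are ordinal. Computed from the
  5×5 crosstab; reported both as a coefficient and ×100 (percentage
  style). When expected disagreement is zero, kappa is 1 for a perfectly
  concordant table and undefined (NaN) otherwise.
- **Chi-square.** Pearson statistic on the 2 × L version-by-letter
  contingency with expecteds from pooled margins, no continuity
  correction; letters empty under both versions are dropped from the
  support (df = L − 1). A warning is emitted when any expected count is
  below 5. Provided both per category and pooled.
- **Multiple testing.** Raw per-category p-values are reported, with
  α = 0.05 used only for labeling, never filtering; no correction is
  applied by default.
- **Color count** is the number of distinct letters observed per category
  under each version — a discrimination measure; it is bounded by [1, 5]
  and, at full market size, does not decrease when generator score
  dispersion is widened (property-tested).

## Problem sizes

Tests run the pipeline on markets of roughly 3–10 % of the full 3432
products (the full size is used where a property needs it, e.g. the
dispersion/color-count test and the default-market size check); the
acceptance script uses a 10 % market for its end-to-end self-check, since
the analytic quantities it reports are exact functions of the band tables
and do not depend on sample size.

## Known limitations

- Band interiors are the official tables, not independently re-derivable
  from the published endpoint spans alone.
- The 2023 algorithm here is the beverage branch only: no general-food
  2022/2023 scale, no alcohol scoring, no red-meat rule, no per-portion
  scoring.
- FVL percentages must be supplied (or parsed from an explicitly declared
  ingredient percentage); when unavailable they default to 0,
  conservatively, mirroring the zero-fiber imputation.
- Ingredient-text sweetener detection is keyword-based (Spanish/English
  list, diacritic-insensitive) and will miss exotic spellings.
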