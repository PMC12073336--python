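"""Paired-comparison statistics for the two algorithm versions.

Scores are small integers, so ties are the norm: the Wilcoxon signed-rank
test here mid-ranks tied absolute differences, drops zero differences
(Wilcoxon's convention; Pratt's available), and uses an exact
tie-aware enumeration for n <= 25 pairs — a dynamic program over doubled
mid-ranks — switching to a tie- and continuity-corrected normal
approximation above. Spearman's rho is the product-moment correlation of
mid-ranks (scipy). Agreement between the two letter assignments uses
Cohen's kappa (unweighted by default; linear weights optional since letters
are ordinal) and a Pearson chi-square on the pooled version-by-letter
contingency table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

LETTERS = ("A", "B", "C", "D", "E")

EXACT_N_MAX = 25  # exact signed-rank distribution up to this many nonzero pairs


def relative_variation(score_2015: float, score_2023: float) -> Optional[float]:
    """((s2023 - s2015) / s2015) * 100; ``None`` (undefined) when s2015 = 0."""
    if score_2015 == 0:
        return None
    return (score_2023 - score_2015) / score_2015 * 100.0


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+: sum of ranks of positive differences
    p_value: float
    n_used: int  # nonzero pairs entering the ranking
    method: str  # "exact" | "approx" | "degenerate"
    degenerate: bool = False


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p over all 2^n sign assignments of the given
    (possibly tied, mid-) ranks, by convolution over doubled ranks."""
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= 2 ** len(r2)
    w2 = int(np.rint(2 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    pairs: Sequence[tuple[float, float]],
    *,
    zero_method: str = "wilcox",
    mode: str = "auto",
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on (score_2015, score_2023) pairs.

    ``zero_method``: "wilcox" drops zero differences before ranking;
    "pratt" ranks them with the rest, then drops their ranks.
    ``mode``: "auto" (exact for n <= 25 nonzero pairs), "exact" or "approx".
    All differences zero -> p = 1 with ``degenerate=True``.
    """
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise ValueError("need a non-empty sequence of (s2015, s2023) pairs")
    d = arr[:, 1] - arr[:, 0]
    nonzero = d != 0
    if not nonzero.any():
        return WilcoxonResult(0.0, 1.0, 0, "degenerate", degenerate=True)

    if zero_method == "wilcox":
        d_used = d[nonzero]
        ranks = sps.rankdata(np.abs(d_used))
    else:  # pratt: rank with zeros included, then drop the zero ranks
        all_ranks = sps.rankdata(np.abs(d))
        ranks = all_ranks[nonzero]
        d_used = d[nonzero]
    n = d_used.size
    w_plus = float(ranks[d_used > 0].sum())

    use_exact = mode == "exact" or (mode == "auto" and n <= EXACT_N_MAX)
    if use_exact:
        return WilcoxonResult(w_plus, _exact_signed_rank_p(ranks, w_plus), n, "exact")

    mu = ranks.sum() / 2.0
    sd = np.sqrt((ranks**2).sum() / 4.0)  # mid-ranks make this tie-corrected
    if sd == 0:
        return WilcoxonResult(w_plus, 1.0, n, "degenerate", degenerate=True)
    diff = w_plus - mu
    z = (diff - 0.5 * np.sign(diff)) / sd  # continuity correction
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return WilcoxonResult(w_plus, p, n, "approx")


@dataclass(frozen=True)
class SpearmanResult:
    rho: Optional[float]  # None when either margin has zero variance
    p_value: Optional[float]
    degenerate: bool = False


def spearman_rho(pairs: Sequence[tuple[float, float]]) -> SpearmanResult:
    """Tie-corrected Spearman rank correlation of the paired scores."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 pairs")
    if np.ptp(arr[:, 0]) == 0 or np.ptp(arr[:, 1]) == 0:
        return SpearmanResult(None, None, degenerate=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.spearmanr(arr[:, 0], arr[:, 1])
    return SpearmanResult(float(res.statistic), float(res.pvalue))


def letter_crosstab(
    records: pd.DataFrame, category: Optional[str] = None
) -> pd.DataFrame:
    """5x5 contingency of (letter_2015 rows, letter_2023 columns).

    ``records`` needs columns letter_2015, letter_2023 (and category when
    filtering). Cells are counts; rows/columns always span A..E.
    """
    df = records if category is None else records[records["category"] == category]
    if df.empty:
        raise ValueError("no records to cross-tabulate")
    tab = pd.crosstab(df["letter_2015"], df["letter_2023"])
    tab = tab.reindex(index=LETTERS, columns=LETTERS, fill_value=0)
    tab.index.name = "letter_2015"
    tab.columns.name = "letter_2023"
    return tab


def crosstab_percentages(tab: pd.DataFrame) -> pd.DataFrame:
    """Marginal letter distributions of both versions as percentage stacks."""
    n = tab.values.sum()
    return pd.DataFrame(
        {
            "pct_2015": tab.sum(axis=1) / n * 100.0,
            "pct_2023": tab.sum(axis=0) / n * 100.0,
        },
        index=list(tab.index),
    ).rename_axis("letter")


def cohen_kappa(crosstab: pd.DataFrame, weights: Optional[str] = None) -> float:
    """Cohen's kappa from a square contingency table.

    ``weights=None`` gives the unweighted kappa; ``"linear"`` weights
    disagreements by their ordinal distance. Returns NaN (flagged undefined)
    when expected agreement is 1 but observed is not.
    """
    m = np.asarray(crosstab, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("crosstab must be square")
    n = m.sum()
    if n <= 0:
        raise ValueError("empty crosstab")
    p = m / n
    rows = p.sum(axis=1)
    cols = p.sum(axis=0)
    k = m.shape[0]
    if weights is None:
        w = 1.0 - np.eye(k)
    elif weights == "linear":
        idx = np.arange(k)
        w = np.abs(idx[:, None] - idx[None, :]) / (k - 1)
    else:
        raise ValueError(f"unknown weights {weights!r}")
    d_obs = (w * p).sum()
    d_exp = (w * np.outer(rows, cols)).sum()
    if d_exp == 0:  # all mass in one (row, col) margin cell
        return 1.0 if d_obs == 0 else float("nan")
    return float(1.0 - d_obs / d_exp)


def chi_square_distribution_test(
    counts_2015: Iterable[int], counts_2023: Iterable[int]
) -> tuple[float, int, float]:
    """Pearson chi-square comparing the two versions' letter distributions.

    Both vectors must span the same letter support; letters empty under both
    versions are dropped; expected counts come from the pooled margins.
    Returns (statistic, df, p) and warns when any expected count is below 5.
    """
    a = np.asarray(list(counts_2015), dtype=float)
    b = np.asarray(list(counts_2023), dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must align over the same letter support")
    if a.sum() + b.sum() == 0:
        raise ValueError("zero total count")
    keep = (a + b) > 0
    table = np.vstack([a[keep], b[keep]])
    if keep.sum() < 2:
        return 0.0, 0, 1.0
    stat, p, df, expected = sps.chi2_contingency(table, correction=False)
    if (expected < 5).any():
        warnings.warn(
            "chi-square expected count below 5; test may be unreliable",
            UserWarning,
            stacklevel=2,
        )
    return float(stat), int(df), float(p)
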