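"""Paired comparison of the 2015 and 2023 algorithms over a product table.

The entry point is :class:`NutriScoreComparison`, built from a
:class:`~nutribev.products.ProductTable` (or a DataFrame / CSV of already
paired scores). ``fit()`` scores every product under both algorithm versions
and returns a :class:`NutriScoreComparisonResults` carrying:

* per-product paired records (scores, letters, relative variation),
* a per-category summary table — medians and ranges of both scores, mean
  relative variation, Wilcoxon signed-rank p, Spearman rho, modal letters,
  Cohen's kappa, per-category chi-square, and the number of distinct letters
  (color count, the label's discriminatory capacity),
* an overall letter-shift table (percentage points per letter) and pooled
  chi-square / kappa,
* long-format score data for box plots, and a minimal box-plot renderer.

Relative variation is ((s2023 - s2015)/s2015) x 100 per product; products
with a zero 2015 score leave it undefined. Three aggregation behaviors are
selectable: ``"exclude-zeros"`` (default: mean over defined values),
``"pratt-style"`` (keep zero-denominator products by substituting a 1-point
denominator), and ``"median-of"`` (variation of the category medians).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import io as nio
from .products import ProductTable
from .scales import get_scale, theoretical_range
from .scoring import score_2015, score_2023
from .stats import (
    LETTERS,
    SpearmanResult,
    WilcoxonResult,
    chi_square_distribution_test,
    cohen_kappa,
    crosstab_percentages,
    letter_crosstab,
    relative_variation,
    spearman_rho,
    wilcoxon_signed_rank,
)

RECORD_COLUMNS = (
    "product_id",
    "category",
    "score_2015",
    "letter_2015",
    "score_2023",
    "letter_2023",
    "relative_variation_pct",
)

RELVAR_MODES = ("exclude-zeros", "pratt-style", "median-of")


def _relvar_aggregate(s15: pd.Series, s23: pd.Series, mode: str) -> tuple[float, int]:
    """(aggregate relative variation %, number of zero-denominator products)."""
    s15 = s15.to_numpy(dtype=float)
    s23 = s23.to_numpy(dtype=float)
    zeros = int((s15 == 0).sum())
    if mode == "exclude-zeros":
        mask = s15 != 0
        if not mask.any():
            return float("nan"), zeros
        return float(np.mean((s23[mask] - s15[mask]) / s15[mask] * 100.0)), zeros
    if mode == "pratt-style":
        denom = np.where(s15 == 0, 1.0, s15)
        return float(np.mean((s23 - s15) / denom * 100.0)), zeros
    if mode == "median-of":
        med15 = float(np.median(s15))
        med23 = float(np.median(s23))
        if med15 == 0:
            return float("nan"), zeros
        return (med23 - med15) / med15 * 100.0, zeros
    raise ValueError(f"unknown relvar mode {mode!r}; expected one of {RELVAR_MODES}")


def build_records(
    table: ProductTable, *, official_protein_rule: bool = False
) -> pd.DataFrame:
    """Score every product under both versions into a paired-record frame."""
    rows = []
    for p in table.rows:
        b15 = score_2015(p, official_protein_rule=official_protein_rule)
        b23 = score_2023(p)
        rv = relative_variation(b15.total_score, b23.total_score)
        rows.append(
            (
                p.product_id,
                p.category,
                b15.total_score,
                b15.letter,
                b23.total_score,
                b23.letter,
                np.nan if rv is None else rv,
            )
        )
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))


def build_summary(
    records: pd.DataFrame,
    *,
    relvar: str = "exclude-zeros",
    kappa: Optional[str] = None,
    zero_method: str = "wilcox",
) -> pd.DataFrame:
    """One summary row per category (medians, ranges, tests, agreement).

    ``kappa`` is ``None`` for unweighted Cohen's kappa or ``"linear"``.
    """
    if records.empty:
        raise ValueError("no records")
    out = []
    for category, grp in records.groupby("category", sort=True):
        pairs = list(zip(grp["score_2015"], grp["score_2023"]))
        wres: WilcoxonResult = wilcoxon_signed_rank(pairs, zero_method=zero_method)
        sres: SpearmanResult = (
            spearman_rho(pairs) if len(pairs) >= 2 else SpearmanResult(None, None, True)
        )
        rv, n_zero = _relvar_aggregate(grp["score_2015"], grp["score_2023"], relvar)
        tab = letter_crosstab(grp)
        counts15 = tab.sum(axis=1).to_numpy()
        counts23 = tab.sum(axis=0).to_numpy()
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            chi_stat, chi_df, chi_p = chi_square_distribution_test(counts15, counts23)
        out.append(
            {
                "category": category,
                "n": len(grp),
                "median_2015": float(grp["score_2015"].median()),
                "min_2015": int(grp["score_2015"].min()),
                "max_2015": int(grp["score_2015"].max()),
                "median_2023": float(grp["score_2023"].median()),
                "min_2023": int(grp["score_2023"].min()),
                "max_2023": int(grp["score_2023"].max()),
                "relative_variation_pct": rv,
                "n_relvar_zero_denominator": n_zero,
                "wilcoxon_statistic": wres.statistic,
                "wilcoxon_p": wres.p_value,
                "spearman_rho": np.nan if sres.rho is None else sres.rho,
                "modal_letter_2015": grp["letter_2015"].mode().sort_values().iloc[0],
                "modal_letter_2023": grp["letter_2023"].mode().sort_values().iloc[0],
                "kappa": cohen_kappa(tab, weights=kappa),
                "kappa_pct": cohen_kappa(tab, weights=kappa) * 100.0,
                "chi2_statistic": chi_stat,
                "chi2_df": chi_df,
                "chi2_p": chi_p,
                "color_count_2015": int(grp["letter_2015"].nunique()),
                "color_count_2023": int(grp["letter_2023"].nunique()),
            }
        )
    return pd.DataFrame(out)


def shift_table(records: pd.DataFrame) -> pd.DataFrame:
    """Percentage of products per letter under each version and the
    percentage-point shift (2023 minus 2015); shifts sum to 0."""
    tab = letter_crosstab(records)
    pct = crosstab_percentages(tab)
    pct["shift_pp"] = pct["pct_2023"] - pct["pct_2015"]
    return pct.reset_index()


def long_format(records: pd.DataFrame) -> pd.DataFrame:
    """Long-format (product, version, score, letter) export for box plots."""
    frames = []
    for version in ("2015", "2023"):
        frames.append(
            pd.DataFrame(
                {
                    "product_id": records["product_id"],
                    "category": records["category"],
                    "version": version,
                    "score": records[f"score_{version}"],
                    "letter": records[f"letter_{version}"],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def letter_cutoffs() -> pd.DataFrame:
    """Upper score cut-off of each letter band under both beverage scales
    (for drawing cut-off lines on score plots)."""
    rows = []
    for name, version in (("beverage_2015", "2015"), ("beverage_2023", "2023")):
        scale = get_scale(name)
        for letter, upper in scale.letter_bands:
            if upper is not None:
                rows.append({"version": version, "letter": letter, "upper_score": upper})
    return pd.DataFrame(rows)


class NutriScoreComparison:
    """Paired 2015-vs-2023 Nutri-Score comparison over a beverage table.

    Parameters
    ----------
    products : ProductTable
        Validated product table (e.g. from
        :func:`nutribev.io.read_products` or
        :func:`nutribev.synthetic.generate_market`).
    relvar : {"exclude-zeros", "pratt-style", "median-of"}
        Aggregation of per-product relative variation (see module docstring).
    kappa : {"cohen", "weighted"}
        Unweighted or linearly weighted Cohen's kappa.
    zero_method : {"wilcox", "pratt"}
        Zero-difference handling in the Wilcoxon signed-rank test.
    official_protein_rule : bool
        Opt into the official 2015 protein-counting exception.

    Examples
    --------
    >>> from nutribev import NutriScoreComparison, generate_market
    >>> market = generate_market(seed=1, scale=0.1)
    >>> res = NutriScoreComparison(market).fit()
    >>> print(res.summary())  # doctest: +SKIP
    """

    def __init__(
        self,
        products: ProductTable,
        *,
        relvar: str = "exclude-zeros",
        kappa: str = "cohen",
        zero_method: str = "wilcox",
        official_protein_rule: bool = False,
    ) -> None:
        if relvar not in RELVAR_MODES:
            raise ValueError(f"relvar must be one of {RELVAR_MODES}")
        if kappa not in ("cohen", "weighted"):
            raise ValueError("kappa must be 'cohen' or 'weighted'")
        self.products = products
        self.relvar = relvar
        self.kappa_flavor = None if kappa == "cohen" else "linear"
        self.zero_method = zero_method
        self.official_protein_rule = official_protein_rule

    @classmethod
    def from_csv(cls, path, **kwargs) -> "NutriScoreComparison":
        """Build from a product composition CSV (see :func:`nutribev.io.read_products`)."""
        return cls(nio.read_products(path), **kwargs)

    @classmethod
    def from_records(cls, records: pd.DataFrame, **kwargs) -> "NutriScoreComparisonResults":
        """Skip scoring: fit directly from an already paired records frame
        (e.g. a scores CSV written by :func:`nutribev.io.write_scores`)."""
        needed = {"product_id", "category", "score_2015", "letter_2015", "score_2023", "letter_2023"}
        missing = needed - set(records.columns)
        if missing:
            raise ValueError(f"records missing columns {sorted(missing)}")
        self = cls.__new__(cls)
        self.products = None
        self.relvar = kwargs.get("relvar", "exclude-zeros")
        kappa = kwargs.get("kappa", "cohen")
        self.kappa_flavor = None if kappa == "cohen" else "linear"
        self.zero_method = kwargs.get("zero_method", "wilcox")
        self.official_protein_rule = kwargs.get("official_protein_rule", False)
        rec = records.copy()
        rec["relative_variation_pct"] = [
            np.nan if relative_variation(a, b) is None else relative_variation(a, b)
            for a, b in zip(rec["score_2015"], rec["score_2023"])
        ]
        return self._finish(rec[list(RECORD_COLUMNS)])

    def fit(self) -> "NutriScoreComparisonResults":
        """Score all products under both versions and assemble the results."""
        records = build_records(
            self.products, official_protein_rule=self.official_protein_rule
        )
        return self._finish(records)

    def _finish(self, records: pd.DataFrame) -> "NutriScoreComparisonResults":
        summary = build_summary(
            records,
            relvar=self.relvar,
            kappa=self.kappa_flavor,
            zero_method=self.zero_method,
        )
        shifts = shift_table(records)
        overall_tab = letter_crosstab(records)
        overall_kappa = cohen_kappa(overall_tab, weights=self.kappa_flavor)
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            chi_stat, chi_df, chi_p = chi_square_distribution_test(
                overall_tab.sum(axis=1).to_numpy(), overall_tab.sum(axis=0).to_numpy()
            )
        return NutriScoreComparisonResults(
            model=self,
            records=records,
            category_table=summary,
            shift_table=shifts,
            overall_kappa=overall_kappa,
            overall_chi2=(chi_stat, chi_df, chi_p),
        )


@dataclass
class NutriScoreComparisonResults:
    """Results of a fitted :class:`NutriScoreComparison`."""

    model: NutriScoreComparison
    records: pd.DataFrame
    category_table: pd.DataFrame
    shift_table: pd.DataFrame
    overall_kappa: float
    overall_chi2: tuple[float, int, float]

    @property
    def nobs(self) -> int:
        return len(self.records)

    def crosstab(self, category: Optional[str] = None) -> pd.DataFrame:
        """5x5 letter contingency (2015 rows x 2023 columns)."""
        return letter_crosstab(self.records, category)

    def long_format(self) -> pd.DataFrame:
        return long_format(self.records)

    def summary(self) -> str:
        """Human-readable summary table, one row per category."""
        df = self.category_table.copy()
        lines = [
            "Nutri-Score 2015 vs 2023 paired comparison",
            "=" * 78,
            f"products: {self.nobs}    categories: {len(df)}",
            f"overall kappa: {self.overall_kappa:.3f}    "
            f"overall chi2: {self.overall_chi2[0]:.2f} "
            f"(df={self.overall_chi2[1]}, p={self.overall_chi2[2]:.3g})",
            "-" * 78,
        ]
        show = df[
            [
                "category",
                "n",
                "median_2015",
                "median_2023",
                "relative_variation_pct",
                "wilcoxon_p",
                "spearman_rho",
                "modal_letter_2015",
                "modal_letter_2023",
                "kappa_pct",
            ]
        ].rename(
            columns={
                "median_2015": "med15",
                "median_2023": "med23",
                "relative_variation_pct": "relvar%",
                "wilcoxon_p": "p(W)",
                "spearman_rho": "rho",
                "modal_letter_2015": "L15",
                "modal_letter_2023": "L23",
                "kappa_pct": "kappa%",
            }
        )
        lines.append(show.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
        lines.append("-" * 78)
        lines.append("letter shifts (percentage points, 2023 - 2015):")
        lines.append(self.shift_table.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
        return "\n".join(lines)

    def to_csv(self, out_dir) -> dict[str, str]:
        """Write summary, records, crosstabs, shift table and long-format
        plot data as CSVs under ``out_dir``; returns {name: path}."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}

        def _write(name: str, df: pd.DataFrame, index: bool = False) -> None:
            p = out / name
            df.to_csv(p, index=index)
            paths[name] = str(p)

        _write("summary.csv", self.category_table)
        _write("records.csv", self.records)
        _write("shift_table.csv", self.shift_table)
        _write("crosstab_overall.csv", self.crosstab(), index=True)
        for cat in sorted(self.records["category"].unique()):
            _write(f"crosstab_{cat}.csv", self.crosstab(cat), index=True)
        plot_df = self.long_format()
        _write("plot_data.csv", plot_df)
        _write("letter_cutoffs.csv", letter_cutoffs())
        return paths

    def plot_box(self, path=None, ax=None):
        """Box plot of score distributions per category and version, with the
        beverage letter cut-offs of both versions as horizontal lines."""
        import matplotlib

        if path is not None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 5))
        cats = sorted(self.records["category"].unique())
        data15 = [self.records.loc[self.records["category"] == c, "score_2015"] for c in cats]
        data23 = [self.records.loc[self.records["category"] == c, "score_2023"] for c in cats]
        pos = np.arange(len(cats))
        ax.boxplot(data15, positions=pos - 0.18, widths=0.3)
        ax.boxplot(data23, positions=pos + 0.18, widths=0.3)
        for _, row in letter_cutoffs().iterrows():
            style = "-" if row["version"] == "2015" else ":"
            ax.axhline(row["upper_score"] + 0.5, linestyle=style, linewidth=0.6, color="gray")
        ax.set_xticks(pos)
        ax.set_xticklabels(cats, rotation=60, ha="right", fontsize=7)
        ax.set_ylabel("total score (left box: 2015, right box: 2023)")
        if path is not None:
            ax.figure.savefig(path, bbox_inches="tight")
            plt.close(ax.figure)
        return ax
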