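"""Reading, validating and writing product composition tables.

Input is a per-product CSV with the nutrient declaration per 100 mL. Energy
may be given in kJ, kcal, or both; kcal is converted (x 4.184) when kJ is
absent, and when both are present but disagree by more than 2 % the kJ value
(the regulated unit) wins with a warning. Missing fiber is imputed to 0 — the
conservative reading of a non-mandatory declaration — and counted. Rows that
violate product invariants are rejected with row-level diagnostics rather
than aborting the read.
"""

from __future__ import annotations

import json
import logging
import re
import unicodedata
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from pydantic import ValidationError

from .products import KCAL_TO_KJ, BeverageProduct, ProductTable
from .scoring import ScoreBreakdown

logger = logging.getLogger("nutribev")

#: Canonical input columns. energy_kcal and ingredients_text are optional;
#: fiber_g may be blank (missing).
REQUIRED_COLUMNS = (
    "product_id",
    "category",
    "sugars_g",
    "total_fat_g",
    "satfat_g",
    "salt_g",
    "protein_g",
)
OPTIONAL_COLUMNS = (
    "energy_kj",
    "energy_kcal",
    "fiber_g",
    "fvl_percent",
    "has_nns",
    "is_water",
    "ingredients_text",
)

_TRUE = {"1", "true", "yes", "si", "sí", "y", "t"}
_FALSE = {"0", "false", "no", "n", "f", ""}

_PERCENT_RE = re.compile(r"(\d+(?:[.,]\d+)?)\s*%")


def _strip_accents(text: str) -> str:
    return "".join(
        c for c in unicodedata.normalize("NFKD", text) if not unicodedata.combining(c)
    )


def default_nns_keywords() -> list[str]:
    """Sweetener keyword list shipped with the package (Spanish + English)."""
    text = resources.files("nutribev.data").joinpath("nns_keywords.json").read_text("utf-8")
    return json.loads(text)["nns_keywords"]


def derive_flags(
    ingredients_text: str, keywords: Optional[Iterable[str]] = None
) -> tuple[bool, Optional[float]]:
    """Derive (has_nns, fvl_percent or None) from an ingredient list.

    Matching is case- and diacritic-insensitive. The FVL percentage is taken
    from an explicitly declared percentage (e.g. "zumo de naranja (100%)")
    when present; otherwise ``None`` is returned and the caller must supply
    it (the reader defaults it to 0, conservatively).
    """
    if not ingredients_text:
        return False, None
    norm = _strip_accents(ingredients_text.lower())
    kws = default_nns_keywords() if keywords is None else list(keywords)
    has_nns = any(_strip_accents(k.lower()) in norm for k in kws)
    m = _PERCENT_RE.search(norm)
    fvl = None
    if m:
        fvl = float(m.group(1).replace(",", "."))
        if not 0 <= fvl <= 100:
            fvl = None
    return has_nns, fvl


def _parse_bool(raw, default: bool = False) -> bool:
    if isinstance(raw, (bool, np.bool_)):
        return bool(raw)
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return default
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"cannot interpret {raw!r} as a boolean")


def _parse_float(raw, column: str, decimal: str = ".") -> Optional[float]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    s = str(raw).strip()
    if s == "":
        return None
    if decimal != ".":
        s = s.replace(decimal, ".")
    try:
        return float(s)
    except ValueError:
        raise ValueError(f"non-numeric value {raw!r} in column {column!r}") from None


def read_products(
    path,
    *,
    sep: str = ",",
    decimal: str = ".",
    column_map: Optional[dict[str, str]] = None,
    nns_keywords: Optional[Iterable[str]] = None,
    energy_tolerance: float = 0.02,
) -> ProductTable:
    """Read a product composition CSV into a validated :class:`ProductTable`.

    ``column_map`` renames input columns to the canonical names. Rows failing
    validation are collected in ``table.rejected`` as ``(line_number,
    message)`` pairs (line numbers count the header as line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, decimal=decimal, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if "energy_kj" not in df.columns and "energy_kcal" not in df.columns:
        raise ValueError(f"{path}: need an energy column (energy_kj or energy_kcal)")

    rows: list[BeverageProduct] = []
    rejected: list[tuple[int, str]] = []
    fiber_imputed = 0
    fvl_defaulted = 0

    def pf(raw, column):
        return _parse_float(raw, column, decimal)

    for idx, rec in enumerate(df.to_dict("records")):
        line = idx + 2  # header is line 1
        try:
            kj = pf(rec.get("energy_kj"), "energy_kj")
            kcal = pf(rec.get("energy_kcal"), "energy_kcal")
            if kj is None and kcal is None:
                raise ValueError("no energy value (energy_kj/energy_kcal both blank)")
            if kj is not None and kcal is not None and kcal > 0:
                if abs(kj - kcal * KCAL_TO_KJ) > energy_tolerance * max(kj, kcal * KCAL_TO_KJ):
                    logger.warning(
                        "line %d: kJ (%.1f) and kcal (%.1f) disagree by >%.0f%%; "
                        "using kJ",
                        line, kj, kcal, 100 * energy_tolerance,
                    )
            energy_kj = kj if kj is not None else kcal * KCAL_TO_KJ

            fiber = pf(rec.get("fiber_g"), "fiber_g")
            if fiber is None:
                fiber = 0.0
                fiber_imputed += 1

            ingredients = str(rec.get("ingredients_text", "") or "")
            nns_derived, fvl_derived = derive_flags(ingredients, nns_keywords)

            has_nns_raw = rec.get("has_nns")
            has_nns = (
                _parse_bool(has_nns_raw)
                if has_nns_raw not in (None, "")
                else nns_derived
            )

            fvl = pf(rec.get("fvl_percent"), "fvl_percent")
            if fvl is None:
                fvl = fvl_derived
            if fvl is None:
                fvl = 0.0
                fvl_defaulted += 1

            product = BeverageProduct(
                product_id=str(rec["product_id"]),
                category=str(rec["category"]).strip(),
                energy_kj=energy_kj,
                sugars_g=pf(rec["sugars_g"], "sugars_g") or 0.0,
                total_fat_g=pf(rec["total_fat_g"], "total_fat_g") or 0.0,
                satfat_g=pf(rec["satfat_g"], "satfat_g") or 0.0,
                salt_g=pf(rec["salt_g"], "salt_g") or 0.0,
                protein_g=pf(rec["protein_g"], "protein_g") or 0.0,
                fiber_g=fiber,
                fvl_percent=fvl,
                has_nns=has_nns,
                is_water=_parse_bool(rec.get("is_water"), False),
            )
            rows.append(product)
        except (ValueError, ValidationError) as exc:
            # ValidationError subclasses ValueError; check it first
            msg = _summ(exc) if isinstance(exc, ValidationError) else str(exc).splitlines()[0]
            rejected.append((line, msg))

    table = ProductTable(
        rows=rows,
        provenance=str(path),
        fiber_imputed_count=fiber_imputed,
        rejected=rejected,
    )
    logger.info(
        "read %s: %d rows, %d fiber imputations, %d fvl defaults, %d rejected",
        path, len(rows), fiber_imputed, fvl_defaulted, len(rejected),
    )
    return table


def _summ(exc: ValidationError) -> str:
    err = exc.errors()[0]
    loc = ".".join(str(x) for x in err["loc"]) or "row"
    return f"{loc}: {err['msg']}"


#: Stable column order of a scores CSV.
SCORE_COLUMNS_BASE = (
    "product_id",
    "category",
    "energy_kj",
    "sugars_g",
    "total_fat_g",
    "satfat_g",
    "salt_g",
    "protein_g",
    "fiber_g",
    "fvl_percent",
    "has_nns",
    "is_water",
    "scale_2015",
    "score_2015",
    "letter_2015",
    "score_2023",
    "letter_2023",
)


def write_scores(
    table: ProductTable,
    breakdowns_2015: Iterable[ScoreBreakdown],
    breakdowns_2023: Iterable[ScoreBreakdown],
    path,
) -> pd.DataFrame:
    """Write one row per product: composition, both totals, both letters and
    per-component points (columns ``p2015_*`` / ``p2023_*``). Returns the
    frame written. The output round-trips: writing, reading back with
    :func:`read_scores` and writing again is byte-identical.
    """
    b15 = {b.product_id: b for b in breakdowns_2015}
    b23 = {b.product_id: b for b in breakdowns_2023}
    ids = [p.product_id for p in table.rows]
    orphans = (set(b15) | set(b23)) - set(ids)
    missing = [i for i in ids if i not in b15 or i not in b23]
    if orphans or missing:
        raise ValueError(
            f"mismatched product sets: {sorted(orphans)} not in table, "
            f"{missing} lack breakdowns"
        )

    comp15 = sorted({c for b in b15.values() for c in b.component_points})
    comp23 = sorted({c for b in b23.values() for c in b.component_points})
    records = []
    for p in table.rows:
        rec = {
            "product_id": p.product_id,
            "category": p.category,
            "energy_kj": p.energy_kj,
            "sugars_g": p.sugars_g,
            "total_fat_g": p.total_fat_g,
            "satfat_g": p.satfat_g,
            "salt_g": p.salt_g,
            "protein_g": p.protein_g,
            "fiber_g": 0.0 if p.fiber_g is None else p.fiber_g,
            "fvl_percent": p.fvl_percent,
            "has_nns": p.has_nns,
            "is_water": p.is_water,
            "scale_2015": b15[p.product_id].scale_used,
            "score_2015": b15[p.product_id].total_score,
            "letter_2015": b15[p.product_id].letter,
            "score_2023": b23[p.product_id].total_score,
            "letter_2023": b23[p.product_id].letter,
        }
        for c in comp15:
            rec[f"p2015_{c}"] = b15[p.product_id].component_points.get(c, "")
        for c in comp23:
            rec[f"p2023_{c}"] = b23[p.product_id].component_points.get(c, "")
        records.append(rec)

    columns = list(SCORE_COLUMNS_BASE) + [f"p2015_{c}" for c in comp15] + [
        f"p2023_{c}" for c in comp23
    ]
    df = pd.DataFrame.from_records(records, columns=columns)
    df.to_csv(path, index=False)
    return df


def read_scores(path) -> pd.DataFrame:
    """Read a scores CSV written by :func:`write_scores`."""
    df = pd.read_csv(path)
    needed = {"product_id", "category", "score_2015", "letter_2015", "score_2023", "letter_2023"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: not a scores CSV, missing {sorted(missing)}")
    return df
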