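"""Stratified disproportionality within the target-drug cohort.

For a stratification factor (sex, age band, reporter class) and each event
term, a within-cohort 2×2 compares event occurrence between two strata::

                       with event    without event
    stratum A               a              b
    stratum B               c              d

so a is the number of stratum-A cases reporting the term and b the
stratum-A cases not reporting it (per-case counting, unlike the case–PT
pair counting of drug-vs-background disproportionality).  Each term gets a
ROR with Wald CI, a Yates χ² p-value, and Benjamini–Hochberg adjusted
p-values across terms; volcano coordinates are x = log2(ROR),
y = −log10(p_adj).

A term is called stratum-A-enriched when ROR > 1 and p_adj is significant,
stratum-B-enriched when ROR < 1 and p_adj is significant, otherwise null.
The conventional significance direction is p_adj < α; the reversed reading
(p_adj > α) that sometimes appears in print is selectable via
``rule="greater"`` but is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .disproportionality import chi_square_components, ror_components
from .faers_ingest import CaseData, MeddraMap, MISSING_LABEL

FACTORS = {
    "sex": ("sex", [("F", "M")]),
    "age_group": ("age_group", None),         # one-vs-rest per band
    "occp_class": ("occp_class", [("Consumer", "Healthcare professional")]),
}


class SubgroupError(ValueError):
    pass


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (same order as input)."""
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise SubgroupError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _term_case_matrix(cases: pd.DataFrame, level: str, meddra_map: MeddraMap | None,
                      terms: Sequence[str] | None) -> tuple[list[str], np.ndarray]:
    """Boolean case × term occurrence matrix."""
    if level == "SOC":
        if meddra_map is None:
            raise SubgroupError("SOC-level subgroup analysis requires a MedDRA map")
        sets = [frozenset(meddra_map.soc_of(pt) for pt in r) for r in cases["reactions"]]
    else:
        sets = list(cases["reactions"])
    if terms is None:
        terms = sorted(set().union(*sets)) if sets else []
    terms = list(terms)
    mat = np.zeros((len(sets), len(terms)), dtype=bool)
    index = {t: j for j, t in enumerate(terms)}
    for i, s in enumerate(sets):
        for t in s:
            j = index.get(t)
            if j is not None:
                mat[i, j] = True
    return terms, mat


def stratified_tables(
    dataset: CaseData,
    factor: str,
    event_terms: Sequence[str] | None = None,
    level: str = "PT",
    meddra_map: MeddraMap | None = None,
) -> pd.DataFrame:
    """Per-term within-cohort 2×2 comparisons for *factor*.

    Cases with a missing factor value are excluded.  Sex compares F vs M;
    occupation compares consumers vs healthcare professionals; age runs
    one-vs-rest for each band.  Raises if either stratum is empty.

    Returns one row per (comparison, term) with columns: stratum_a,
    stratum_b, term, a, b, c, d, ror, ror_low95, ror_high95, p_value.
    """
    if factor not in FACTORS:
        raise SubgroupError(f"factor must be one of {sorted(FACTORS)}, got {factor!r}")
    col, pairs = FACTORS[factor]
    cohort = dataset.target
    cohort = cohort[cohort["analyzable"]]
    values = cohort[col].astype(str)
    valid = ~values.isin(["", MISSING_LABEL])
    cohort = cohort[valid]
    values = values[valid]

    if pairs is None:  # one-vs-rest per observed band
        bands = sorted(values.unique())
        pairs = [(band, f"not {band}") for band in bands]

    terms, mat = _term_case_matrix(cohort, level, meddra_map, event_terms)
    out_rows = []
    for stratum_a, stratum_b in pairs:
        in_a = (values == stratum_a).to_numpy()
        in_b = (values == stratum_b).to_numpy() if not stratum_b.startswith("not ") else ~in_a
        if in_a.sum() == 0:
            raise SubgroupError(f"stratum {stratum_a!r} has zero cases")
        if in_b.sum() == 0:
            raise SubgroupError(f"stratum {stratum_b!r} has zero cases")
        a = mat[in_a].sum(axis=0)
        c = mat[in_b].sum(axis=0)
        b = int(in_a.sum()) - a
        d = int(in_b.sum()) - c
        ror, lo, hi = ror_components(a, b, c, d)
        _, p = chi_square_components(a, b, c, d)
        for j, term in enumerate(terms):
            out_rows.append({
                "stratum_a": stratum_a, "stratum_b": stratum_b, "term": term,
                "a": int(a[j]), "b": int(b[j]), "c": int(c[j]), "d": int(d[j]),
                "ror": float(ror[j]), "ror_low95": float(lo[j]),
                "ror_high95": float(hi[j]), "p_value": float(p[j]),
            })
    return pd.DataFrame(out_rows)


def volcano_coordinates(
    results: pd.DataFrame,
    alpha: float = 0.05,
    rule: str = "less",
) -> pd.DataFrame:
    """Add FDR adjustment, volcano coordinates and enrichment classes.

    BH adjustment runs within each (stratum_a, stratum_b) comparison.
    x = log2(ROR), y = −log10(p_adj); p_adj of exactly 0 is clipped to the
    smallest positive float and flagged in ``p_adj_clipped``.
    """
    if rule not in ("less", "greater"):
        raise SubgroupError("rule must be 'less' (conventional) or 'greater'")
    out = results.copy()
    out["p_adj"] = np.nan
    for _, idx in out.groupby(["stratum_a", "stratum_b"]).groups.items():
        out.loc[idx, "p_adj"] = fdr_adjust(out.loc[idx, "p_value"].to_numpy())
    clipped = out["p_adj"] == 0.0
    tiny = np.nextafter(0.0, 1.0)
    out["p_adj_clipped"] = clipped
    p_adj = out["p_adj"].where(~clipped, tiny)
    out["x"] = np.log2(out["ror"])
    out["y"] = -np.log10(p_adj)
    significant = (out["p_adj"] < alpha) if rule == "less" else (out["p_adj"] > alpha)
    classes = np.where(
        significant & (out["ror"] > 1), out["stratum_a"] + "-enriched",
        np.where(significant & (out["ror"] < 1), out["stratum_b"] + "-enriched", "null"),
    )
    out["classification"] = classes
    return out


def sex_subgroup_analysis(
    dataset: CaseData,
    event_terms: Sequence[str] | None = None,
    level: str = "PT",
    meddra_map: MeddraMap | None = None,
    alpha: float = 0.05,
    rule: str = "less",
) -> pd.DataFrame:
    """F-vs-M stratified disproportionality with volcano output."""
    tables = stratified_tables(dataset, "sex", event_terms, level, meddra_map)
    return volcano_coordinates(tables, alpha=alpha, rule=rule)
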