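"""Trait lookups of lead variants in external GWAS summary statistics.

For each (lead variant, trait) pair the external Z score (beta/SE) is
aligned to the counted (A2) allele; availability, suggestive (p < 0.05)
and FDR-significant (BH-adjusted p < 0.05) flags reproduce a PheWAS-style
heatmap table. The FDR family is the full grid of available tests.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PALINDROMIC = {frozenset({"A", "T"}), frozenset({"C", "G"})}


def align_z(
    a1: str, a2: str, effect_allele: str, other_allele: str, beta: float, se: float
) -> tuple[float, str]:
    """Z score aligned to the query's counted allele (A2).

    Returns (Z, flag); Z is NaN with flag 'allele_mismatch' when the
    allele sets differ. Palindromic pairs are aligned by label but
    flagged 'ambiguous'.
    """
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    if se <= 0 or not np.isfinite(se):
        raise ValueError("standard error must be positive")
    query = {a1.upper(), a2.upper()}
    record = {effect_allele.upper(), other_allele.upper()}
    if query != record:
        return float("nan"), "allele_mismatch"
    z = beta / se
    if effect_allele.upper() != a2.upper():
        z = -z
    flag = "ambiguous" if frozenset(query) in PALINDROMIC else ""
    return float(z), flag


def fdr_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def trait_lookup(
    leads: pd.DataFrame,
    trait_stats: dict[str, pd.DataFrame],
    suggestive_alpha: float = 0.05,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Build the variant x trait lookup table.

    ``leads`` needs columns lead_rsID, A1, A2. Each trait's summary
    statistics need id, effect_allele, other_allele, beta, se, p. FDR is
    applied once across all available (variant, trait) cells.
    """
    rows = []
    for _, lead in leads.iterrows():
        rsid = lead["lead_rsID"] if "lead_rsID" in lead else lead["rsID"]
        for trait, ss in trait_stats.items():
            rec = ss[ss["id"] == rsid]
            row = {
                "rsID": rsid,
                "trait": trait,
                "available": False,
                "Z": np.nan,
                "P": np.nan,
                "flag": "missing_variant",
                "suggestive": False,
                "significant": False,
            }
            if not rec.empty:
                r = rec.iloc[0]
                z, flag = align_z(
                    str(lead["A1"]), str(lead["A2"]),
                    str(r["effect_allele"]), str(r["other_allele"]),
                    float(r["beta"]), float(r["se"]),
                )
                if np.isfinite(z):
                    p = float(r["p"]) if "p" in r and np.isfinite(r["p"]) else float(
                        2 * stats.norm.sf(abs(z))
                    )
                    row.update({"available": True, "Z": z, "P": p, "flag": flag})
                else:
                    row["flag"] = flag
            rows.append(row)
    table = pd.DataFrame(rows)
    avail = table["available"].to_numpy()
    if avail.any():
        adj = np.full(len(table), np.nan)
        adj[avail] = fdr_bh(table.loc[avail, "P"].to_numpy())
        table["P_fdr"] = adj
        table.loc[avail, "suggestive"] = table.loc[avail, "P"] < suggestive_alpha
        table.loc[avail, "significant"] = table.loc[avail, "P_fdr"] < fdr_alpha
    else:
        table["P_fdr"] = np.nan
    return table
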