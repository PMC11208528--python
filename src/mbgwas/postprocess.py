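"""Significance calling, locus grouping, LD, gene annotation, diagnostics.

Associations are flagged at the genome-wide threshold (P <= 5e-8) and at
a study-wide threshold (genome-wide / number of scans by default, or an
explicit configured value). Significant variants are grouped greedily
into 1 Mb loci around lead variants, annotated with the nearest gene, and
summarized with Manhattan/QQ tables and the genomic-inflation factor.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CHI2_1_MEDIAN = 0.4549364231195724  # median of chi-square with 1 df


def apply_thresholds(
    assoc: pd.DataFrame,
    alpha_gw: float = 5e-8,
    n_tests: int = 1,
    alpha_sw: float | None = None,
) -> pd.DataFrame:
    """Flag genome-wide (p <= alpha_gw) and study-wide significance.

    The study-wide threshold defaults to alpha_gw / n_tests and may be
    pinned explicitly via ``alpha_sw``. Both comparisons are inclusive.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    threshold_sw = alpha_gw / n_tests if alpha_sw is None else alpha_sw
    out = assoc.copy()
    p = out["P"].to_numpy(dtype=float)
    out["genome_wide"] = p <= alpha_gw
    out["study_wide"] = p <= threshold_sw
    out.attrs["alpha_genome_wide"] = alpha_gw
    out.attrs["alpha_study_wide"] = threshold_sw
    return out


def group_loci(significant: pd.DataFrame, window_bp: int = 1_000_000) -> pd.DataFrame:
    """Greedy 1 Mb locus grouping around lead variants.

    Repeatedly the unassigned variant with the smallest p becomes a lead;
    unassigned significant variants on its chromosome within half the
    window on either side join its locus. Ties on p break by position,
    then id. Output: one row per locus with members listed.
    """
    if significant.empty:
        return pd.DataFrame(
            columns=["locus", "Chromosome", "start", "end", "lead_rsID", "lead_P",
                     "lead_EffectSize", "A1", "A2", "members", "n_members"]
        )
    half = window_bp // 2
    df = significant.reset_index(drop=True).copy()
    order = df.sort_values(["P", "Position", "rsID"], kind="mergesort").index
    assigned = np.zeros(len(df), dtype=bool)
    loci = []
    for idx in order:
        if assigned[idx]:
            continue
        lead = df.loc[idx]
        same = (
            ~assigned
            & (df["Chromosome"] == lead["Chromosome"]).to_numpy()
            & (np.abs(df["Position"].to_numpy() - lead["Position"]) <= half)
        )
        members = df.loc[same]
        assigned |= same
        loci.append(
            {
                "locus": len(loci),
                "Chromosome": lead["Chromosome"],
                "start": int(members["Position"].min()),
                "end": int(members["Position"].max()),
                "lead_rsID": lead["rsID"],
                "lead_P": lead["P"],
                "lead_EffectSize": lead.get("EffectSize", np.nan),
                "A1": lead.get("A1", ""),
                "A2": lead.get("A2", ""),
                "members": ",".join(members["rsID"].astype(str)),
                "n_members": int(same.sum()),
            }
        )
    return pd.DataFrame(loci)


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over pairwise-complete samples; undefined (NaN) when either
    vector is constant on that subset.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = ~np.isnan(g1) & ~np.isnan(g2)
    a, b = g1[ok], g2[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def genomic_inflation(pvals: np.ndarray) -> float:
    """Genomic inflation factor: median association chi-square / 0.4549."""
    p = np.asarray(pvals, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def nearest_gene(
    chromosome: str, position: int, genes: pd.DataFrame
) -> tuple[str | None, float]:
    """Nearest gene to a position; distance 0 inside a gene.

    ``genes`` uses 1-based inclusive start/end (BED converted on read).
    Ties break by smaller start coordinate; an empty chromosome yields
    (None, NaN) with a warning.
    """
    sub = genes[genes["chrom"].astype(str) == str(chromosome)]
    if sub.empty:
        logger.warning("no genes on chromosome %s; nearest gene unavailable", chromosome)
        return None, float("nan")
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    dist = np.where(
        (position >= starts) & (position <= ends),
        0,
        np.minimum(np.abs(position - starts), np.abs(position - ends)),
    )
    best = np.lexsort((starts, dist))[0]
    return str(sub.iloc[best]["name"]), float(dist[best])


def annotate_loci(loci: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    out = loci.copy()
    names, dists = [], []
    for _, row in out.iterrows():
        lead_pos = (row["start"] + row["end"]) // 2 if "lead_Position" not in row else row["lead_Position"]
        name, d = nearest_gene(row["Chromosome"], lead_pos, genes)
        names.append(name)
        dists.append(d)
    out["nearest_gene"] = names
    out["gene_distance_bp"] = dists
    return out


def manhattan_table(assoc: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready Manhattan data: chromosome, position, p, feature."""
    cols = ["Chromosome", "Position", "P"]
    extra = [c for c in ["TaxonName"] if c in assoc.columns]
    return assoc[cols + extra].copy()


def qq_table(pvals: np.ndarray) -> pd.DataFrame:
    """Expected vs observed -log10 p for a QQ plot."""
    p = np.sort(np.asarray(pvals, dtype=float))
    p = p[~np.isnan(p)]
    n = p.size
    if n == 0:
        raise ValueError("no p-values supplied")
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(np.clip(p, np.finfo(float).tiny, 1.0))
    return pd.DataFrame({"expected": expected, "observed": observed})
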