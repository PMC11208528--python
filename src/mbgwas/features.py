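"""Univariate bacterial feature construction.

ASVs are agglomerated to every taxonomic rank, filtered on prevalence
(present in more than 100 participants) and abundance (median count over
present samples above 50), de-redundified by complete-linkage clustering
on Spearman correlation (cutoff 0.985), and represented by the most
specific taxon per cluster. The number of clusters is the number of
univariate association scans.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .containers import AGG_RANKS, RANK_DEPTH, RANKS, CountTable, FeatureSet

logger = logging.getLogger(__name__)


def aggregate_taxa(counts: CountTable, rank: str) -> CountTable:
    """Sum ASV counts sharing the lineage prefix down to ``rank``.

    Features unassigned at ``rank`` are grouped by their longest assigned
    prefix and flagged with an ``_unassigned`` suffix. Per-sample totals
    are conserved exactly.
    """
    if rank not in AGG_RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {AGG_RANKS}")
    upto = RANKS[: RANKS.index(rank) + 1]
    tax = counts.taxonomy

    groups: dict[str, dict] = {}
    assign = {}
    for fid in counts.features:
        row = tax.loc[fid]
        values = [str(row[r]) for r in upto]
        if values[-1]:
            lineage = ";".join(v for v in values if v)
            flagged = False
        else:
            prefix = [v for v in values if v]
            lineage = ";".join(prefix) + f";_unassigned_{rank}"
            flagged = True
        assign[fid] = lineage
        if lineage not in groups:
            lin_full = {r: (str(row[r]) if r in upto else "") for r in RANKS}
            groups[lineage] = {
                "lineage": lineage,
                "rank": rank,
                "flagged_unassigned": flagged,
                **lin_full,
            }

    agg = counts.counts.T.groupby(pd.Series(assign)).sum().T
    new_tax = pd.DataFrame.from_dict(groups, orient="index").loc[list(agg.columns)]
    return CountTable(counts=agg, taxonomy=new_tax)


def build_candidates(counts: CountTable) -> CountTable:
    """Concatenate ASV-level features with every aggregated rank."""
    tables = [counts] + [aggregate_taxa(counts, r) for r in AGG_RANKS]
    parts, taxes = [], []
    for t in tables:
        parts.append(t.counts)
        taxes.append(t.taxonomy)
    merged = pd.concat(parts, axis=1)
    tax = pd.concat(taxes, axis=0)
    # an ASV that is the sole member of its species/genus... duplicates the
    # aggregated column id only if ids collide; lineage-named columns differ
    # from ASV ids by construction
    return CountTable(counts=merged, taxonomy=tax)


def filter_features(
    counts: CountTable, min_prevalence: int = 100, min_median: float = 50
) -> FeatureSet:
    """Prevalence and abundance filters, both strict.

    A feature is kept iff it is present (count > 0) in more than
    ``min_prevalence`` samples AND the median count over the samples where
    it is present exceeds ``min_median``.
    """
    mat = counts.counts
    prevalence = (mat > 0).sum(axis=0)
    med_present = mat.apply(lambda col: col[col > 0].median() if (col > 0).any() else 0.0)
    kept = (prevalence > min_prevalence) & (med_present > min_median)

    log_rows = []
    for fid in mat.columns:
        if kept[fid]:
            log_rows.append({"feature": fid, "action": "kept", "reason": "passed_filters"})
        else:
            reasons = []
            if prevalence[fid] <= min_prevalence:
                reasons.append(f"prevalence {prevalence[fid]} <= {min_prevalence}")
            if med_present[fid] <= min_median:
                reasons.append(f"nonzero_median {med_present[fid]} <= {min_median}")
            log_rows.append({"feature": fid, "action": "dropped", "reason": "; ".join(reasons)})
    table = pd.DataFrame(
        {
            "rank": counts.taxonomy["rank"],
            "lineage": counts.taxonomy["lineage"],
            "prevalence": prevalence,
            "median_present": med_present,
            "total": mat.sum(axis=0),
            "kept": kept,
            "cluster": -1,
            "selected": False,
        },
        index=mat.columns,
    )
    logger.info("feature filter: %d/%d kept", int(kept.sum()), len(kept))
    return FeatureSet(table=table, log=pd.DataFrame(log_rows))


def spearman_matrix(mat: np.ndarray) -> np.ndarray:
    """Pairwise Spearman rho across columns, average ranks for ties."""
    ranks = np.apply_along_axis(rankdata, 0, mat)
    ranks = ranks - ranks.mean(axis=0)
    norms = np.sqrt((ranks**2).sum(axis=0))
    safe = np.where(norms > 0, norms, 1.0)
    rho = (ranks.T @ ranks) / np.outer(safe, safe)
    rho[norms == 0, :] = np.nan
    rho[:, norms == 0] = np.nan
    np.fill_diagonal(rho, 1.0)
    return rho


def cluster_features(
    candidates: FeatureSet, counts: CountTable, rho_cutoff: float = 0.985
) -> FeatureSet:
    """Complete-linkage clustering on 1 - Spearman rho, cut at 1 - cutoff.

    Complete linkage guarantees that every within-cluster pair satisfies
    rho >= rho_cutoff. Zero-variance features become logged singletons.
    """
    fs = FeatureSet(table=candidates.table.copy(), log=candidates.log.copy())
    kept_ids = list(fs.table.index[fs.table["kept"]])
    if not kept_ids:
        return fs
    mat = counts.counts[kept_ids].to_numpy(dtype=float)
    rho = spearman_matrix(mat)
    zero_var = mat.std(axis=0) == 0

    ok = ~zero_var
    labels = np.full(len(kept_ids), -1, dtype=int)
    next_label = 0
    if ok.sum() == 1:
        labels[ok] = next_label
        next_label += 1
    elif ok.sum() > 1:
        sub = rho[np.ix_(ok, ok)]
        dist = 1.0 - sub
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        Z = sch.linkage(squareform(dist, checks=False), method="complete")
        flat = sch.fcluster(Z, t=1.0 - rho_cutoff, criterion="distance")
        labels[ok] = flat - 1
        next_label = int(flat.max())
    extra_logs = []
    for i in np.where(zero_var)[0]:
        labels[i] = next_label
        next_label += 1
        extra_logs.append(
            {"feature": kept_ids[i], "action": "singleton", "reason": "zero_variance"}
        )
    fs.table.loc[kept_ids, "cluster"] = labels
    if extra_logs:
        fs.log = pd.concat([fs.log, pd.DataFrame(extra_logs)], ignore_index=True)
    logger.info("clustered %d features into %d clusters", len(kept_ids), next_label)
    return fs


def select_representatives(clustered: FeatureSet) -> FeatureSet:
    """Pick the most specific taxon per cluster.

    Rank depth orders phylum < ... < species < ASV ("lowest taxonomic
    group" = most specific). Ties at equal depth break by highest total
    count, then lexicographic feature id.
    """
    fs = FeatureSet(table=clustered.table.copy(), log=clustered.log.copy())
    fs.table["selected"] = False
    in_cluster = fs.table[fs.table["cluster"] >= 0]
    for _, members in in_cluster.groupby("cluster"):
        depth = members["rank"].map(RANK_DEPTH)
        best = members.assign(_depth=depth).sort_values(
            by=["_depth", "total"], ascending=[False, False], kind="mergesort"
        )
        top_depth, top_total = best.iloc[0]["_depth"], best.iloc[0]["total"]
        ties = best[(best["_depth"] == top_depth) & (best["total"] == top_total)]
        rep = sorted(ties.index)[0]
        fs.table.loc[rep, "selected"] = True
    return fs


def build_feature_set(
    counts: CountTable,
    min_prevalence: int = 100,
    min_median: float = 50,
    rho_cutoff: float = 0.985,
) -> FeatureSet:
    """Full feature construction: aggregate, filter, cluster, select."""
    candidates = build_candidates(counts)
    fs = filter_features(candidates, min_prevalence, min_median)
    fs = cluster_features(fs, candidates, rho_cutoff)
    return select_representatives(fs)


def n_scans(fs: FeatureSet, include_beta_diversity: bool = True) -> int:
    """Number of association scans: one per cluster plus the beta-diversity scan."""
    return fs.n_clusters + (1 if include_beta_diversity else 0)
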