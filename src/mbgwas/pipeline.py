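"""End-to-end orchestration of the association scans.

One univariate abundance scan per selected bacterial feature plus one
beta-diversity scan; the scan count (clusters + 1) sets the default
study-wide significance threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import abundance, beta, features as feat, postprocess
from .containers import CountTable, CovariateTable, FeatureSet, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    feature_set: FeatureSet
    abundance_results: dict[str, pd.DataFrame]
    beta_result: pd.DataFrame | None
    qc_report: pd.DataFrame
    n_scans: int
    diagnostics: dict = field(default_factory=dict)


def run_pipeline(
    G: GenotypeMatrix,
    counts: CountTable,
    covariates: CovariateTable,
    config: dict,
    seed: int = 0,
    include_beta: bool = True,
    feature_set: FeatureSet | None = None,
) -> PipelineResult:
    """Run feature construction and every association scan.

    The abundance arm uses MAF/call-rate/HWE QC; the beta-diversity arm
    additionally requires imputation R2 above its configured minimum.
    """
    if feature_set is None:
        feature_set = feat.build_feature_set(
            counts,
            min_prevalence=config["min_prevalence"],
            min_median=config["min_median"],
            rho_cutoff=config["spearman_cutoff"],
        )
    n_scans = feat.n_scans(feature_set, include_beta_diversity=include_beta)
    logger.info("planned scans: %d (%d clusters + %d beta-diversity)",
                n_scans, feature_set.n_clusters, int(include_beta))

    keep_ab, qc_report = abundance.variant_qc(
        G,
        maf_min=config["maf_min"],
        callrate_min=config["callrate_min"],
        hwe_alpha=config["hwe_alpha"],
    )

    candidates = feat.build_candidates(counts)
    ab_results: dict[str, pd.DataFrame] = {}
    diagnostics: dict = {"lambda_gc": {}}
    for fid, row in feature_set.selected.iterrows():
        try:
            assoc = abundance.abundance_gwas(
                candidates,
                covariates,
                G,
                fid,
                keep_mask=keep_ab,
                seed=seed,
                taxon_name=row["lineage"],
                taxon_level=row["rank"],
            )
        except RuntimeError as exc:
            logger.warning("feature %s excluded from scans: %s", fid, exc)
            continue
        ab_results[fid] = assoc
        pv = assoc["P"].dropna()
        if len(pv):
            diagnostics["lambda_gc"][fid] = postprocess.genomic_inflation(pv.to_numpy())

    beta_result = None
    if include_beta:
        keep_beta, _ = abundance.variant_qc(
            G,
            maf_min=config["maf_min"],
            callrate_min=config["callrate_min"],
            hwe_alpha=config["hwe_alpha"],
            r2_min=config["imputation_r2_min"],
        )
        rare = beta.rarefy(counts, depth=config["rarefaction_depth"], seed=seed)
        D = beta.bray_curtis(rare)
        Gw = beta.gower_center(D)
        cov_complete = [s for s in covariates.complete_samples() if s in Gw.samples]
        if cov_complete != Gw.samples:
            mask = np.array([s in cov_complete for s in Gw.samples])
            Gw = beta._recentered_subset(Gw, mask)
        X = covariates.design_matrix(Gw.samples)
        G_res = beta.partial_out_covariates(Gw, X)
        beta_result = beta.snp_scan_beta(
            G_res,
            G,
            keep_mask=keep_beta,
            n_moment_perm=config["dbf_moment_permutations"],
            seed=seed,
        )
        pv = beta_result["P"].dropna()
        if len(pv):
            diagnostics["lambda_gc"]["beta_diversity"] = postprocess.genomic_inflation(
                pv.to_numpy()
            )

    return PipelineResult(
        feature_set=feature_set,
        abundance_results=ab_results,
        beta_result=beta_result,
        qc_report=qc_report,
        n_scans=n_scans,
        diagnostics=diagnostics,
    )


def significant_hits(result: PipelineResult, config: dict) -> pd.DataFrame:
    """Pool all scans, apply thresholds, and return flagged associations."""
    frames = list(result.abundance_results.values())
    if result.beta_result is not None:
        frames.append(result.beta_result)
    if not frames:
        return pd.DataFrame()
    pooled = pd.concat(frames, ignore_index=True)
    flagged = postprocess.apply_thresholds(
        pooled.dropna(subset=["P"]),
        alpha_gw=config["alpha_genome_wide"],
        n_tests=result.n_scans,
        alpha_sw=config["alpha_study_wide"],
    )
    return flagged
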