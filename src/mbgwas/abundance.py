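"""Univariate abundance GWAS.

Two stages per bacterial feature: (1) a zero-truncated negative-binomial
GLM of raw counts on host covariates with log(total sample reads) as
offset; (2) randomized-quantile (Dunn-Smyth) residuals from that fit are
regressed on each QC-passing variant's 0/1/2 dosage in a simple linear
model. Variant QC applies MAF, call-rate, Hardy-Weinberg and (optionally)
imputation-quality filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

from .containers import CountTable, CovariateTable, GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int, midp: bool = False) -> float:
    """Exact two-sided Hardy-Weinberg p-value.

    Enumerates every heterozygote count compatible with the observed
    allele counts and sums the conditional probabilities of all
    configurations no more probable than the observed one. With ``midp``
    only half the observed configuration's probability is counted — the
    mid-p variant is nearly uniform under the null and suits calibration
    diagnostics, while the default conservative p is used for filtering.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotyped samples")
    n_alt = 2 * n_hom_alt + n_het
    n_ref = 2 * n_hom_ref + n_het
    rare = min(n_alt, n_ref)
    # heterozygote counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = (n - hets - hom_rare).astype(int)
    # log P(het | allele counts) up to a shared constant:
    #   n! / (hom_c! het! hom_r!) * 2^het  (multinomial over genotypes x
    #   2 phases per het), normalized below
    logw = (
        hets * np.log(2.0)
        - special.gammaln(hom_common + 1)
        - special.gammaln(hets + 1)
        - special.gammaln(hom_rare + 1)
    )
    w = np.exp(logw - logw.max())
    probs = w / w.sum()
    obs = np.flatnonzero(hets == n_het)
    if obs.size == 0:  # inconsistent counts cannot occur for valid input
        raise ValueError("observed heterozygote count incompatible with alleles")
    p_obs = probs[obs[0]]
    tail = probs[probs <= p_obs * (1 + 1e-12)].sum()
    if midp:
        tail -= 0.5 * p_obs
    return float(min(1.0, tail))


# ---------------------------------------------------------------------------
# variant QC


def variant_qc(
    G: GenotypeMatrix,
    maf_min: float = 0.05,
    callrate_min: float = 0.95,
    hwe_alpha: float = 0.005,
    r2_min: float | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Keep-mask plus per-variant QC report.

    A variant passes iff MAF > maf_min (strict), call rate > callrate_min
    (strict), HWE exact p >= hwe_alpha, and — when ``r2_min`` is given —
    imputation R2 > r2_min (variants without an R2 value are treated as
    directly genotyped and pass that filter).
    """
    dos = G.dosage
    n = dos.shape[0]
    obs = ~np.isnan(dos)
    n_called = obs.sum(axis=0)
    callrate = n_called / n
    with np.errstate(invalid="ignore"):
        alt_freq = np.nansum(dos, axis=0) / np.maximum(2 * n_called, 1)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)

    hwe_p = np.ones(dos.shape[1])
    for j in range(dos.shape[1]):
        if n_called[j] == 0:
            hwe_p[j] = np.nan
            continue
        col = dos[obs[:, j], j]
        n_ref = int((col == 0).sum())
        n_het = int((col == 1).sum())
        n_alt = int((col == 2).sum())
        hwe_p[j] = hwe_exact_p(n_ref, n_het, n_alt)

    report = pd.DataFrame(
        {
            "id": G.variants["id"].to_numpy(),
            "call_rate": callrate,
            "maf": np.where(n_called > 0, maf, np.nan),
            "hwe_p": hwe_p,
            "imputation_r2": G.variants["imputation_r2"].to_numpy(),
        }
    )
    no_calls = n_called == 0
    fail_maf = ~no_calls & ~(maf > maf_min)
    fail_call = ~(callrate > callrate_min)
    fail_hwe = ~no_calls & ~(hwe_p >= hwe_alpha)
    reasons = []
    keep = np.ones(dos.shape[1], dtype=bool)
    fail_r2 = np.zeros(dos.shape[1], dtype=bool)
    if r2_min is not None:
        r2 = G.variants["imputation_r2"].to_numpy(dtype=float)
        fail_r2 = ~np.isnan(r2) & ~(r2 > r2_min)
    for j in range(dos.shape[1]):
        why = []
        if no_calls[j]:
            why.append("no_calls")
        if fail_maf[j]:
            why.append("maf")
        if fail_call[j]:
            why.append("call_rate")
        if fail_hwe[j]:
            why.append("hwe")
        if fail_r2[j]:
            why.append("imputation_r2")
        reasons.append(";".join(why))
        keep[j] = not why
    report["keep"] = keep
    report["drop_reason"] = reasons
    logger.info(
        "variant QC: %d/%d kept (maf %d, call_rate %d, hwe %d, r2 %d, no_calls %d dropped)",
        int(keep.sum()),
        len(keep),
        int(fail_maf.sum()),
        int(fail_call.sum()),
        int(fail_hwe.sum()),
        int(fail_r2.sum()),
        int(no_calls.sum()),
    )
    return keep, report


# ---------------------------------------------------------------------------
# negative-binomial GLM (Var = mu + mu^2 / theta)


@dataclass
class NBFit:
    coefficients: pd.Series
    theta: float
    fitted_mu: np.ndarray
    offset: np.ndarray
    converged: bool
    n_used: int
    samples: list[str]


def _nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    return float(
        np.sum(
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def fit_nb_glm(
    y: np.ndarray,
    X: pd.DataFrame | np.ndarray,
    offset: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> NBFit:
    """Joint ML fit of a log-link NB regression and its dispersion.

    Alternates IRLS for the regression coefficients (given theta) with a
    one-dimensional maximization of the profile likelihood in log(theta),
    until both increments fall below ``tol``. ``y`` must already be the
    zero-truncated subset (all counts positive) with complete covariates.
    """
    y = np.asarray(y, dtype=float)
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(np.asarray(X).shape[1])]
    samples = list(X.index) if isinstance(X, pd.DataFrame) else [str(i) for i in range(len(y))]
    Xa = np.asarray(X, dtype=float)
    offset = np.asarray(offset, dtype=float)
    if (y <= 0).any():
        raise ValueError("fit_nb_glm expects the zero-truncated subset (all y > 0)")
    if len(y) <= Xa.shape[1]:
        raise ValueError("more coefficients than observations")

    theta = 1.0
    beta = None
    converged = False
    for _ in range(max_iter):
        fam = sm.families.NegativeBinomial(alpha=1.0 / theta)
        model = sm.GLM(y, Xa, family=fam, offset=offset)
        try:
            res = model.fit(start_params=beta, maxiter=200, tol=1e-10)
        except Exception:
            res = model.fit(maxiter=200, tol=1e-10)
        new_beta = res.params
        mu = np.exp(Xa @ new_beta + offset)

        def negll(log_theta: float) -> float:
            return -_nb_loglik(y, mu, float(np.exp(log_theta)))

        opt = optimize.minimize_scalar(
            negll, bounds=(np.log(1e-4), np.log(1e7)), method="bounded",
            options={"xatol": 1e-12},
        )
        new_theta = float(np.exp(opt.x))
        d_beta = np.inf if beta is None else np.max(np.abs(new_beta - beta))
        d_theta = abs(np.log(new_theta) - np.log(theta))
        beta, theta = new_beta, new_theta
        if d_beta < tol and d_theta < tol:
            converged = True
            break
    mu = np.exp(Xa @ beta + offset)
    return NBFit(
        coefficients=pd.Series(beta, index=names),
        theta=theta,
        fitted_mu=mu,
        offset=offset,
        converged=converged,
        n_used=len(y),
        samples=samples,
    )


def fit_taxon_model(
    counts: CountTable,
    covariates: CovariateTable,
    feature: str,
    sample_totals: pd.Series | None = None,
) -> NBFit:
    """Zero-truncated NB fit of one feature on the full covariate design.

    Samples with a zero count or any missing covariate are excluded; the
    offset is the log of each sample's total sequence count (row sum of
    the ASV table unless supplied).
    """
    totals = counts.sample_totals() if sample_totals is None else sample_totals
    y_all = counts.counts[feature]
    eligible = [
        s
        for s in covariates.complete_samples()
        if s in y_all.index and y_all[s] > 0 and totals[s] > 0
    ]
    n_dropped = len(y_all) - len(eligible)
    if n_dropped:
        logger.debug("feature %s: %d samples excluded (zero count or incomplete covariates)", feature, n_dropped)
    X = covariates.design_matrix(eligible)
    y = y_all.loc[eligible].to_numpy(dtype=float)
    offset = np.log(totals.loc[eligible].to_numpy(dtype=float))
    return fit_nb_glm(y, X, offset)


# ---------------------------------------------------------------------------
# randomized-quantile residuals


@dataclass
class ResidualVector:
    values: pd.Series
    residual_type: str
    seed: int | None


def dunn_smyth_residuals(fit: NBFit, y: np.ndarray, seed: int = 0) -> ResidualVector:
    """Randomized-quantile residuals for an NB fit.

    r_i = Phi^{-1}(u_i) with u_i uniform on (F(y_i - 1), F(y_i)] under the
    fitted NB distribution; standard normal when the model is correct.
    """
    y = np.asarray(y, dtype=float)
    theta, mu = fit.theta, fit.fitted_mu
    p_nb = theta / (theta + mu)
    upper = stats.nbinom.cdf(y, theta, p_nb)
    lower = np.where(y > 0, stats.nbinom.cdf(y - 1, theta, p_nb), 0.0)
    rng = np.random.default_rng(seed)
    u = lower + rng.uniform(size=y.shape) * (upper - lower)
    u = np.clip(u, 1e-12, 1 - 1e-12)
    r = stats.norm.ppf(u)
    return ResidualVector(
        values=pd.Series(r, index=fit.samples), residual_type="dunn_smyth", seed=seed
    )


def pearson_residuals(fit: NBFit, y: np.ndarray) -> ResidualVector:
    y = np.asarray(y, dtype=float)
    mu = fit.fitted_mu
    r = (y - mu) / np.sqrt(mu + mu**2 / fit.theta)
    return ResidualVector(values=pd.Series(r, index=fit.samples), residual_type="pearson", seed=None)


# ---------------------------------------------------------------------------
# per-variant linear scan


def snp_scan_univariate(
    residuals: ResidualVector,
    G: GenotypeMatrix,
    keep_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """OLS of residuals on each variant's dosage; beta is per alt-allele copy.

    Samples missing a genotype at a variant are dropped for that variant
    only. Monomorphic variants in the analysis subset get a missing p with
    reason; a zero-residual (perfect) fit is flagged ``degenerate_fit``
    with p reported at the zero limit.
    """
    sample_idx = [G.samples.index(s) for s in residuals.values.index if s in G.samples]
    used_samples = [G.samples[i] for i in sample_idx]
    r = residuals.values.loc[used_samples].to_numpy(dtype=float)
    dos = G.dosage[sample_idx, :]
    variants = G.variants
    if keep_mask is not None:
        dos = dos[:, keep_mask]
        variants = variants.loc[np.asarray(keep_mask)].reset_index(drop=True)

    M = ~np.isnan(dos)
    Gz = np.where(M, dos, 0.0)
    n_v = M.sum(axis=0).astype(float)
    sg = Gz.sum(axis=0)
    sgg = (Gz**2).sum(axis=0)
    sr = M.T @ r
    srr = M.T @ (r**2)
    sgr = Gz.T @ r
    with np.errstate(invalid="ignore", divide="ignore"):
        sxx = sgg - sg**2 / n_v
        sxy = sgr - sg * sr / n_v
        syy = srr - sr**2 / n_v
        beta = sxy / sxx
        rss = syy - beta * sxy
        df = n_v - 2
        sigma2 = rss / df
        se = np.sqrt(sigma2 / sxx)
        t = beta / se
        p = 2.0 * stats.t.sf(np.abs(t), df)

    flags = np.array([""] * len(n_v), dtype=object)
    mono = sxx <= 0
    degen = ~mono & (rss <= 1e-12 * np.maximum(syy, 1.0)) & (df > 0)
    flags[mono] = "monomorphic"
    flags[degen] = "degenerate_fit"
    beta[mono] = np.nan
    se[mono] = np.nan
    t[mono] = np.nan
    p[mono] = np.nan
    p[degen] = 0.0
    out = pd.DataFrame(
        {
            "Chromosome": variants["chrom"].to_numpy(),
            "Position": variants["pos"].to_numpy(),
            "P": p,
            "EffectSize": beta,
            "A1": variants["ref"].to_numpy(),
            "A2": variants["alt"].to_numpy(),
            "StandardError": se,
            "rsID": variants["id"].to_numpy(),
            "t": t,
            "n": n_v.astype(int),
            "flag": flags,
        }
    )
    return out


def abundance_gwas(
    counts: CountTable,
    covariates: CovariateTable,
    G: GenotypeMatrix,
    feature: str,
    keep_mask: np.ndarray | None = None,
    seed: int = 0,
    taxon_name: str | None = None,
    taxon_level: str | None = None,
) -> pd.DataFrame:
    """Full two-stage scan for one bacterial feature."""
    fit = fit_taxon_model(counts, covariates, feature)
    if not fit.converged:
        raise RuntimeError(f"NB fit did not converge for feature {feature}")
    y = counts.counts.loc[fit.samples, feature].to_numpy(dtype=float)
    resid = dunn_smyth_residuals(fit, y, seed=seed)
    assoc = snp_scan_univariate(resid, G, keep_mask)
    assoc["TaxonName"] = taxon_name if taxon_name is not None else feature
    assoc["TaxonLevel"] = taxon_level if taxon_level is not None else "feature"
    return assoc
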