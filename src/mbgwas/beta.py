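"""Beta-diversity GWAS via a distance-based F-test.

Counts are rarefied to even depth, Bray-Curtis dissimilarities are
Gower-centered into an inner-product matrix, host covariates are
partialled out by projecting onto their residual space, and each variant
is tested with a PERMANOVA-style pseudo-F whose null is approximated by a
Pearson type III distribution fitted to permutation moments (an exact
permutation p-value is available for validation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearson3, skew

from .containers import CountTable, GenotypeMatrix

logger = logging.getLogger(__name__)


def rarefy(counts: CountTable, depth: int = 5000, seed: int = 0) -> CountTable:
    """Subsample each sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped and logged.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    totals = counts.sample_totals()
    keep = totals[totals >= depth].index
    dropped = sorted(set(counts.samples) - set(keep))
    if dropped:
        logger.info("rarefaction: dropped %d samples below depth %d: %s",
                    len(dropped), depth, dropped[:5])
    mat = counts.counts.loc[keep].to_numpy()
    out = np.empty_like(mat)
    for i in range(mat.shape[0]):
        out[i] = rng.multivariate_hypergeometric(mat[i], depth)
    rare = pd.DataFrame(out, index=keep, columns=counts.counts.columns)
    return CountTable(counts=rare, taxonomy=counts.taxonomy)


def bray_curtis(counts: CountTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity: sum|u-v| / sum(u+v)."""
    mat = counts.counts.to_numpy(dtype=float)
    if mat.shape[0] < 2:
        raise ValueError("need at least two samples")
    zero = mat.sum(axis=1) == 0
    if zero.any():
        bad = [counts.samples[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"all-zero samples have undefined Bray-Curtis: {bad}")
    D = squareform(pdist(mat, metric="braycurtis"))
    return pd.DataFrame(D, index=counts.samples, columns=counts.samples)


@dataclass
class GowerMatrix:
    """Doubly centered inner-product matrix G = J(-1/2 D^2)J.

    ``n_covariates`` counts the non-intercept covariate columns already
    projected out of G (0 before partialling); it sets the denominator
    degrees of freedom of the distance-based F-test.
    """

    values: np.ndarray
    samples: list[str]
    n_covariates: int = 0

    @property
    def n(self) -> int:
        return len(self.samples)


def gower_center(D: pd.DataFrame) -> GowerMatrix:
    """Gower-center a dissimilarity matrix: G = J A J, A = -D∘D/2."""
    Dm = np.asarray(D, dtype=float)
    if not np.allclose(Dm, Dm.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    n = Dm.shape[0]
    A = -0.5 * Dm**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    G = (G + G.T) / 2.0
    return GowerMatrix(values=G, samples=list(D.index))


def partial_out_covariates(G: GowerMatrix, X: pd.DataFrame) -> GowerMatrix:
    """Project covariate-explained variation out of a Gower matrix.

    G_res = R G R with R = I - X(X'X)^-1 X'; X must include an intercept
    and be full column rank (collinear columns are reported).
    """
    Xa = np.asarray(X, dtype=float)
    if Xa.shape[0] != G.n:
        raise ValueError("covariate rows do not match Gower matrix")
    q, r = np.linalg.qr(Xa)
    diag = np.abs(np.diag(r))
    bad = diag < 1e-10 * max(diag.max(), 1.0)
    if bad.any():
        cols = [X.columns[i] for i in np.flatnonzero(bad)] if hasattr(X, "columns") else list(np.flatnonzero(bad))
        raise ValueError(f"rank-deficient covariate design; collinear columns: {cols}")
    R = np.eye(G.n) - q @ q.T
    G_res = R @ G.values @ R
    G_res = (G_res + G_res.T) / 2.0
    return GowerMatrix(values=G_res, samples=G.samples, n_covariates=Xa.shape[1] - 1)


@dataclass
class DBFResult:
    pseudo_F: float
    p_analytic: float
    p_perm: float | None
    n_perm: int
    method: str
    numerator_trace: float


def _recentered_subset(G: GowerMatrix, mask: np.ndarray) -> GowerMatrix:
    """Row/column subset of G with centering recomputed on the subset."""
    sub = G.values[np.ix_(mask, mask)]
    n = sub.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    sub = J @ sub @ J
    sub = (sub + sub.T) / 2.0
    return GowerMatrix(
        values=sub,
        samples=[s for s, m in zip(G.samples, mask) if m],
        n_covariates=G.n_covariates,
    )


def dbf_test(
    G_res: GowerMatrix,
    g: np.ndarray,
    n_perm: int | None = None,
    n_moment_perm: int = 2000,
    seed: int = 0,
    method: str = "pearson3",
) -> DBFResult:
    """Distance-based F-test of a single genotype vector.

    With x the centered dosage and H = xx'/(x'x), the statistic is

        pseudo_F = tr(H G H) / [ tr((I-H) G (I-H)) / (n - q - 2) ]

    where q covariate columns were already projected out of G. Both traces
    reduce to s = x'Gx/x'x and tr(G) - s. The analytic p-value fits a
    Pearson type III distribution to the mean, variance and skewness of s
    over ``n_moment_perm`` label permutations of g; an exact permutation
    p-value over ``n_perm`` permutations is returned when requested.
    """
    g = np.asarray(g, dtype=float)
    n = G_res.n
    if g.shape[0] != n:
        raise ValueError("genotype length does not match Gower matrix")
    if np.nanstd(g) == 0:
        raise ValueError("monomorphic genotype vector")
    q = G_res.n_covariates
    df_den = n - q - 2
    if df_den <= 0:
        raise ValueError(f"non-positive denominator df (n={n}, q={q})")

    x = g - g.mean()
    xtx = float(x @ x)
    Gm = G_res.values
    trG = float(np.trace(Gm))
    s_obs = float(x @ Gm @ x) / xtx
    denom = trG - s_obs
    pseudo_F = s_obs / (denom / df_den) if denom > 0 else np.inf

    rng = np.random.default_rng(seed)
    n_mp = max(int(n_moment_perm), 1000)
    perm_idx = np.argsort(rng.random((n_mp, n)), axis=1)
    Xp = x[perm_idx]  # (n_mp, n)
    s_perm = np.einsum("ij,ij->i", Xp @ Gm, Xp) / xtx
    m1 = float(s_perm.mean())
    sd = float(s_perm.std(ddof=1))
    g1 = float(skew(s_perm, bias=False))
    if sd <= 0:
        p_analytic = 1.0
    else:
        p_analytic = float(pearson3.sf(s_obs, g1, loc=m1, scale=sd))
        p_analytic = float(np.clip(p_analytic, np.finfo(float).tiny, 1.0))

    p_perm = None
    used_perm = 0
    if n_perm:
        perm_idx2 = np.argsort(rng.random((int(n_perm), n)), axis=1)
        Xp2 = x[perm_idx2]
        s2 = np.einsum("ij,ij->i", Xp2 @ Gm, Xp2) / xtx
        p_perm = float((1 + np.sum(s2 >= s_obs - 1e-12)) / (1 + int(n_perm)))
        used_perm = int(n_perm)
    return DBFResult(
        pseudo_F=float(pseudo_F),
        p_analytic=p_analytic,
        p_perm=p_perm,
        n_perm=used_perm,
        method=method,
        numerator_trace=s_obs,
    )


def snp_scan_beta(
    G_res: GowerMatrix,
    G: GenotypeMatrix,
    keep_mask: np.ndarray | None = None,
    n_moment_perm: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """DBF-test of every QC-passing variant against the residual Gower matrix.

    Per variant the analysis subset is the intersection of distance-matrix
    samples and non-missing genotypes; the Gower matrix is subset and
    re-centered on that subset before testing.
    """
    sample_idx = np.array([G.samples.index(s) for s in G_res.samples])
    dos = G.dosage[sample_idx, :]
    variants = G.variants
    if keep_mask is not None:
        dos = dos[:, keep_mask]
        variants = variants.loc[np.asarray(keep_mask)].reset_index(drop=True)

    rows = []
    for j in range(dos.shape[1]):
        g = dos[:, j]
        obs = ~np.isnan(g)
        rec = {
            "Chromosome": variants.at[j, "chrom"],
            "Position": variants.at[j, "pos"],
            "rsID": variants.at[j, "id"],
            "A1": variants.at[j, "ref"],
            "A2": variants.at[j, "alt"],
            "n": int(obs.sum()),
        }
        try:
            sub = G_res if obs.all() else _recentered_subset(G_res, obs)
            res = dbf_test(
                sub, g[obs], n_moment_perm=n_moment_perm, seed=seed + j, n_perm=None
            )
            rec.update({"pseudo_F": res.pseudo_F, "P": res.p_analytic, "flag": ""})
        except ValueError as exc:
            rec.update({"pseudo_F": np.nan, "P": np.nan, "flag": str(exc)})
            logger.debug("variant %s skipped: %s", rec["rsID"], exc)
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["EffectSize"] = np.nan  # the DBF-test is omnibus; no per-allele beta
    out["StandardError"] = np.nan
    out["TaxonName"] = "beta_diversity"
    out["TaxonLevel"] = "community"
    return out
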