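"""Synthetic cohort generator.

Emulates the data structure the association pipeline assumes: HWE
genotypes with block LD and missingness, a covariate table matching the
cohort's descriptive moments (middle-aged Danish adults, ~610 of them),
and negative-binomial taxon counts with a log link, covariate effects,
optional per-allele SNP effects, and per-sample sequencing depth entering
as an offset. A truth table records the planted effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import RANKS, CountTable, CovariateTable, GenotypeMatrix


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults state the emulated world: 610 samples (the cohort size),
    common variants (MAF 5-50%) in 10-variant LD blocks with haplotype
    copy probability 0.8, 1% missing calls, 150 ASVs nested into a
    five-level taxonomy, sequencing depth LogNormal(log 20000, 0.4) so
    nearly all samples clear the 5000-read rarefaction depth, and
    negative-binomial dispersion theta = 2 (Var = mu + mu^2/theta).
    """

    n_samples: int = 610
    n_variants: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.01
    ld_block_size: int = 10
    ld_rho: float = 0.8
    n_asv: int = 150
    depth_lognormal: tuple[float, float] = (math.log(20000.0), 0.4)
    dispersion_theta: float = 2.0
    covariate_effect_sd: float = 0.1
    snp_effects: list[tuple[int, int, float]] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0 or self.n_variants <= 0 or self.n_asv <= 0:
            raise ValueError("sample/variant/ASV counts must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.dispersion_theta <= 0:
            raise ValueError("dispersion_theta must be positive")
        if not (0 <= self.ld_rho <= 1):
            raise ValueError("ld_rho must be in [0, 1]")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")


@dataclass
class TruthTable:
    """Planted (variant index, taxon index, per-allele beta) triples."""

    planted: pd.DataFrame  # columns: variant, taxon, beta
    null_variants: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return self.planted.copy()


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw HWE genotypes with haplotype-copy LD and random missingness.

    Per variant, the MAF is uniform on ``cfg.maf_range`` and genotypes are
    Binomial(2, p). Within an LD block each variant copies the previous
    variant's allele per haplotype with probability ``ld_rho``, otherwise
    redraws Bernoulli(p) — marginal allele frequencies are exact while
    adjacent variants correlate.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n, m = cfg.n_samples, cfg.n_variants
    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    hap = np.empty((2, n, m), dtype=np.int8)
    for j in range(m):
        fresh = rng.random((2, n)) < mafs[j]
        if j % cfg.ld_block_size == 0:
            hap[:, :, j] = fresh
        else:
            copy = rng.random((2, n)) < cfg.ld_rho
            hap[:, :, j] = np.where(copy, hap[:, :, j - 1], fresh)
    dosage = hap.sum(axis=0).astype(float)
    if cfg.missing_rate > 0:
        miss = rng.random((n, m)) < cfg.missing_rate
        dosage[miss] = np.nan
    variants = pd.DataFrame(
        {
            "chrom": [str(1 + j * 22 // m) for j in range(m)],
            "pos": [1_000_000 + 5_000 * j for j in range(m)],
            "id": [f"rs{j:06d}" for j in range(m)],
            "ref": "A",
            "alt": "G",
            "imputation_r2": np.round(rng.uniform(0.7, 1.0, size=m), 4),
        }
    )
    samples = [f"S{i:04d}" for i in range(n)]
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


# Table-1 anchored covariate moments: age 67.6 (6.0) y, BMI 26.9 (4.2)
# kg/m2, 333/610 men, smoking ex/non/current 17.0/47.4/35.6 %, glycemic
# states at the cohort's proportions.
_SMOKING_LEVELS = ["non-smoker", "ex-smoker", "smoker"]
_SMOKING_P = [0.474, 0.170, 0.356]
_GLYCEMIC_LEVELS = ["NGT", "IFG", "IGT", "IFG_IGT", "screen_T2D", "T2D"]
_GLYCEMIC_P = [0.565, 0.161, 0.079, 0.084, 0.093, 0.018]


def simulate_covariates(cfg: SimConfig, rng: np.random.Generator | None = None) -> CovariateTable:
    """Covariates with the cohort's marginal structure.

    Alcohol is weekly units, Gamma(2, 3.5) (right-skewed, mean 7);
    genetic PCs are standard normal.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    n = cfg.n_samples
    data = {
        "sex": rng.choice(["female", "male"], size=n, p=[277 / 610, 333 / 610]),
        "age": rng.normal(67.6, 6.0, size=n),
        "bmi": rng.normal(26.9, 4.2, size=n),
        "smoking": rng.choice(_SMOKING_LEVELS, size=n, p=_SMOKING_P),
        "alcohol": rng.gamma(2.0, 3.5, size=n),
        "glycemic_state": rng.choice(_GLYCEMIC_LEVELS, size=n, p=_GLYCEMIC_P),
        "seq_run": rng.choice(["R1", "R2"], size=n),
    }
    for i in range(1, 11):
        data[f"pc{i}"] = rng.normal(0.0, 1.0, size=n)
    df = pd.DataFrame(data, index=[f"S{i:04d}" for i in range(n)])
    return CovariateTable(data=df)


def default_taxonomy(n_asv: int, rng: np.random.Generator) -> pd.DataFrame:
    """Random nested taxonomy: ASVs -> genera -> families -> orders -> classes -> phyla."""
    n_genus = max(2, n_asv // 4)
    n_family = max(2, n_genus // 2)
    n_order = max(2, n_family // 2)
    n_class = max(2, n_order // 2)
    n_phylum = max(2, min(5, n_class))
    genus_of = rng.integers(0, n_genus, size=n_asv)
    family_of_genus = rng.integers(0, n_family, size=n_genus)
    order_of_family = rng.integers(0, n_order, size=n_family)
    class_of_order = rng.integers(0, n_class, size=n_order)
    phylum_of_class = rng.integers(0, n_phylum, size=n_class)
    rows = []
    for a in range(n_asv):
        g = genus_of[a]
        f = family_of_genus[g]
        o = order_of_family[f]
        c = class_of_order[o]
        p = phylum_of_class[c]
        rows.append(
            {
                "kingdom": "Bacteria",
                "phylum": f"Phylum{p:02d}",
                "class": f"Class{c:02d}",
                "order": f"Order{o:02d}",
                "family": f"Family{f:02d}",
                "genus": f"Genus{g:02d}",
                "species": f"Species{a:03d}",
            }
        )
    tax = pd.DataFrame(rows, index=[f"ASV{a:04d}" for a in range(n_asv)])
    tax["rank"] = "asv"
    tax["lineage"] = tax[RANKS].apply(lambda r: ";".join(v for v in r if v), axis=1)
    return tax


def simulate_counts(
    G: GenotypeMatrix,
    X: CovariateTable,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CountTable, TruthTable]:
    """Negative-binomial taxon counts with log-link covariate and SNP effects.

    Per sample i: depth N_i ~ LogNormal(cfg.depth_lognormal). Per taxon j:
    y_ij ~ NB(mu_ij, theta) with

        log mu_ij = alpha_j + x_i' gamma_j + beta_vj * g_iv + log N_i

    where alpha_j is a log relative abundance, gamma_j are small covariate
    effects on standardized covariates, and the beta terms come from
    ``cfg.snp_effects``. Missing genotypes at a planted variant are mean-
    imputed for generation only. Baseline relative abundances are
    log-normally spread and normalized to sum to one, so expected totals
    track the drawn sequencing depth.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    n = G.n_samples
    if X.data.shape[0] != n:
        raise ValueError("genotype and covariate sample counts differ")
    m_taxa = cfg.n_asv
    depth = rng.lognormal(cfg.depth_lognormal[0], cfg.depth_lognormal[1], size=n)

    design = X.design_matrix().to_numpy()[:, 1:]  # drop intercept
    design = (design - design.mean(axis=0)) / np.where(design.std(axis=0) > 0, design.std(axis=0), 1.0)

    weights = rng.lognormal(0.0, 1.5, size=m_taxa)
    alpha = np.log(weights / weights.sum())
    gamma = rng.normal(0.0, cfg.covariate_effect_sd, size=(design.shape[1], m_taxa))

    eta = alpha[None, :] + design @ gamma + np.log(depth)[:, None]
    for v, j, beta in cfg.snp_effects:
        g = G.dosage[:, v]
        obs = g[~np.isnan(g)]
        if obs.size == 0 or np.all(obs == obs[0]):
            raise ValueError(f"planted variant {v} is monomorphic")
        g_filled = np.where(np.isnan(g), obs.mean(), g)
        eta[:, j] = eta[:, j] + beta * g_filled

    mu = np.exp(eta)
    theta = cfg.dispersion_theta
    counts = rng.negative_binomial(theta, theta / (theta + mu))
    taxonomy = default_taxonomy(m_taxa, rng)
    table = CountTable(
        counts=pd.DataFrame(counts, index=G.samples, columns=list(taxonomy.index)),
        taxonomy=taxonomy,
    )
    planted = pd.DataFrame(cfg.snp_effects, columns=["variant", "taxon", "beta"])
    null_variants = np.setdiff1d(np.arange(G.n_variants), planted["variant"].to_numpy())
    return table, TruthTable(planted=planted, null_variants=null_variants)


def simulate_cohort(
    cfg: SimConfig,
) -> tuple[GenotypeMatrix, CovariateTable, CountTable, TruthTable]:
    """Full cohort: genotypes, covariates, counts, truth, from one seed."""
    rng = np.random.default_rng(cfg.seed)
    G = simulate_genotypes(cfg, rng)
    X = simulate_covariates(cfg, rng)
    counts, truth = simulate_counts(G, X, cfg, rng)
    return G, X, counts, truth
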