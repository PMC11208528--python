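# Methods

This note records the statistical model behind each stage, the defaults
and why they hold, the numerical choices, and what the synthetic-cohort
generator does and does not emulate.

## Feature construction

Candidate features are the ASVs plus their agglomerations at every rank
from species up to phylum; agglomeration sums counts over features
sharing the lineage prefix and conserves per-sample totals exactly.
Features unassigned at the target rank are grouped under their longest
assigned prefix and flagged rather than discarded, so the conservation
invariant holds at every rank.

Two strict filters follow: a feature is kept only if it is present
(count > 0) in **more than 100 samples** and the **median count over the
samples where it is present exceeds 50**. The median is taken over
present samples only: in a ~600-sample cohort an all-sample median above
50 would force presence in more than half the cohort and make the
prevalence filter vacuous, so the present-sample reading is the one
under which both filters do work. Both comparisons are strict, so a
feature at exactly 100 samples or median exactly 50 is dropped.

Redundancy between nested taxa (a genus that is 95% one ASV, etc.) is
removed by complete-linkage hierarchical clustering on 1 − Spearman ρ
(average-rank ties), cutting the tree at 1 − 0.985. Complete linkage is
chosen because it is the only standard linkage that *guarantees* every
within-cluster pair satisfies ρ ≥ 0.985, which the tests assert directly
on the output. Correlation is computed on raw counts (signed ρ, not
|ρ|): the redundancy being removed is positive by construction, and the
downstream model consumes raw counts with an offset. Zero-variance
features cannot be ranked and become logged singleton clusters. Within
each cluster the representative is the feature at the most specific
rank (ASV below species); ties break by higher total count, then
lexicographic id — the tie-break is not dictated by the procedure's
origin and is simply fixed so that the pipeline is deterministic.

The number of clusters equals the number of univariate scans; with the
beta-diversity scan the total scan count feeds the study-wide threshold.

## Abundance model

Counts are "zero-truncated" by excluding zero-count samples before a
standard (untruncated-likelihood) negative-binomial fit, matching the
behaviour of the manyglm-style workflow this pipeline follows rather
than a truncated-NB likelihood. The difference matters only through the
residuals, which remain well-calibrated in the null simulations (see
tests). The NB is parameterized as Var = μ + μ²/θ; the fit alternates
IRLS for the coefficients (statsmodels GLM with fixed θ) with a bounded
one-dimensional maximization of the profile likelihood in log θ
(θ ∈ [1e-4, 1e7]), declaring convergence when both the max coefficient
increment and |Δ log θ| fall below 1e-8 (200 alternations maximum).
Non-convergent fits are flagged and the feature is excluded from scans
with a log entry. The offset is the log of the sample's total sequence
count across all ASVs.

Residuals are randomized-quantile (Dunn–Smyth): r = Φ⁻¹(u) with u
uniform on (F(y−1), F(y)] under the fitted NB, u clipped to
[1e-12, 1−1e-12], drawn from a seeded generator so runs are
reproducible. Under a correct model these are exactly standard normal,
which makes the second-stage OLS t-test calibrated; Pearson residuals
are available as a configuration alternative but are skewed for
low-count taxa.

The per-variant scan is closed-form OLS of the residual on (1, dosage),
with per-variant complete cases (a sample missing only this genotype is
dropped only here). The slope is reported for the alternate (A2) allele;
flipping ref/alt negates the slope and t and leaves p unchanged.
Monomorphic variants yield a missing p with a reason; a numerically
perfect fit (RSS ≈ 0) is flagged `degenerate_fit` with p at the zero
limit rather than NaN.

## Variant QC

MAF is min(f_alt, 1−f_alt) over non-missing calls; call rate is the
non-missing fraction; the Hardy–Weinberg test is the exact conditional
enumeration over heterozygote counts given the allele counts, summing
the probabilities of configurations no more probable than the observed
one. Keep requires MAF > 0.05 (strict), call rate > 0.95 (strict),
HWE p ≥ 0.005, and — in the beta-diversity arm — imputation R² > 0.6.
Variants without an R² value are treated as directly genotyped and pass
the R² filter. Every drop is attributed to the filters it failed.

The exact HWE p-value is discrete and conservative (its null
distribution is stochastically larger than uniform), so a two-sided KS
test against uniform *must* reject it even for a perfect generator; the
generator-calibration diagnostic therefore uses the mid-p variant of the
same enumeration (`hwe_exact_p(..., midp=True)`), which is nearly
uniform, while filtering keeps the conservative p.

## Beta-diversity model

Rarefaction draws exactly `depth` (default 5000) reads per sample
without replacement (multivariate hypergeometric); shallower samples are
dropped and logged, and the rarefaction seed is a first-class
configuration value. Bray–Curtis dissimilarity, Gower centering, and
covariate partialling (G_res = R G R, R built from a QR decomposition of
the intercept-bearing design; rank deficiency is an error naming the
collinear columns) proceed as in the README. Negative PCoA eigenvalues —
Bray–Curtis is non-Euclidean — are retained inside G with no
Lingoes/Cailliez correction, matching the default behaviour of
distance-based redundancy analysis on raw dissimilarities.

The pseudo-F uses denominator degrees of freedom n − q − 2, where q is
the number of non-intercept covariate columns already projected out:
this choice makes the Euclidean, no-covariate special case equal the
classical regression F exactly (asserted to 1e-8 in tests), and is
configurable in principle by adjusting `n_covariates` on the Gower
object. When genotypes are missing, the Gower matrix is subset *and
re-centred on the subset* before testing — the trace identities only
hold when centering matches the tested sample set.

The analytic null is a Pearson type III (shifted gamma) distribution
fitted to the mean, variance and skewness of the numerator trace over
seeded label permutations of the genotype; the numerator is a monotone
function of F given the fixed total trace, so tail probabilities agree.
The moment sample defaults to 2000 permutations in scans; the validity
suite compares the analytic p against a 10⁴-permutation p using a 2×10⁴
moment sample, because at ~10³ permutations the Monte-Carlo error of the
fitted moments alone is comparable to the 0.02 agreement band and would
confound the assessment of the approximation itself (whose error is
measured below 0.003). An exact permutation p,
(1 + #{F_perm ≥ F_obs})/(1 + B), is available for any test.

## Significance, loci, lookups

Genome-wide significance is P ≤ 5e-8 (inclusive). The study-wide
threshold defaults to 5e-8 divided by the number of scans and can be
pinned explicitly in configuration — cohort publications sometimes print
a rounded divisor, and reproducing their labels requires honouring the
printed value rather than recomputing it. Significant variants are
grouped greedily: the smallest-p unassigned variant leads a locus and
absorbs unassigned significant variants on its chromosome within ±500 kb
(a 1 Mb window); ties break by position then id. The output partitions
the significant set. Loci are named by nearest gene (distance 0 inside a
gene; ties by smaller start), LD between members is the squared Pearson
correlation of dosages over pairwise-complete samples, and λ_GC is the
median association χ²(1) divided by 0.4549.

Lead variants are looked up in user-supplied external GWAS summary
statistics (normalized TSV schema: id, effect_allele, other_allele,
beta, se, p). Z = beta/se is aligned to the query's counted (A2) allele,
sign-flipped when the record's effect allele is the other allele, and
declared missing on allele-set mismatch; palindromic (A/T, C/G) pairs
are aligned by label but flagged ambiguous — no strand inference is
attempted. FDR (Benjamini–Hochberg step-up) is applied once across the
whole grid of available (variant, trait) cells, the single-family
convention of a PheWAS heatmap with one significance legend.

## Synthetic cohort

The generator states one world and the tests measure it:

- **Genotypes**: per variant, MAF ~ Uniform(0.05, 0.5); haplotypes drawn
  Bernoulli(p) under HWE; within an LD block (default 10 variants) each
  variant copies the previous haplotype allele with probability 0.8,
  which preserves exact marginal MAF while inducing block LD; 1% missing
  calls. 610 samples by default (the emulated cohort size).
- **Covariates**: sex 333/610 male, age ~ N(67.6, 6.0²) years, BMI ~
  N(26.9, 4.2²) kg/m², smoking 47.4/17.0/35.6% non/ex/current, glycemic
  state at the cohort's six-level proportions, alcohol ~ Gamma(2, 3.5)
  weekly units (right-skewed, mean 7 — a plausible Danish-adult intake;
  the emulated cohort reports no alcohol moments), sequencing run 50/50,
  PCs ~ N(0,1).
- **Counts**: depth ~ LogNormal(log 20000, 0.4) so nearly all samples
  clear 5000-read rarefaction; baseline relative abundances log-normally
  spread (σ = 1.5) and normalized to sum to 1; covariate effects
  N(0, 0.1²) on standardized covariates; planted per-allele SNP effects
  of 0.2–0.7 on the log-mean scale (the scale suggested by residual-unit
  effect sizes around 0.3–0.65 in published cohorts); NB dispersion
  θ = 2.

Not emulated: population structure and admixture (the PCs carry no real
ancestry signal), recombination-map realism, zero inflation beyond what
the NB produces, taxon–taxon interaction, and batch effects beyond a
label. A green calibration test therefore establishes that the pipeline
is correct *under its own model assumptions* — unmodelled real-data
features (structure, zero inflation, compositional coupling) could still
inflate or deflate real scans.

Scale notes: the calibration and power suites run at n = 600 samples and
2000 variants (minutes on one CPU) rather than cohort-scale 5M imputed
variants; the statistics are per-variant, so variant count affects only
Monte-Carlo resolution, not calibration.
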