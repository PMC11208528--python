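"""Core in-memory containers shared across the pipeline.

The pipeline moves three kinds of per-sample data around: hard-called
genotype dosages (0/1/2 alternate-allele copies, NaN for missing), an
ASV/taxon count table with its taxonomic lineage, and a covariate table
with the host variables used for adjustment. All three keep their sample
order explicit so that alignment is always by identifier, never by
position alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Taxonomic ranks from coarsest to finest, as used in 16S lineages.
RANKS = ["kingdom", "phylum", "class", "order", "family", "genus", "species"]

#: Ranks at which agglomerated features may be built (kingdom excluded).
AGG_RANKS = ["phylum", "class", "order", "family", "genus", "species"]

#: Ordering used when picking the most specific ("lowest") rank; ASVs sit
#: below species.
RANK_DEPTH = {r: i for i, r in enumerate(RANKS)}
RANK_DEPTH["asv"] = len(RANKS)

#: Covariates adjusted for in every model: host phenotype/lifestyle
#: variables, sequencing run, and ten genetic principal components.
CATEGORICAL_COVARIATES = ["sex", "smoking", "glycemic_state", "seq_run"]
NUMERIC_COVARIATES = ["age", "bmi", "alcohol"] + [f"pc{i}" for i in range(1, 11)]
COVARIATE_COLUMNS = ["sex", "age", "bmi", "smoking", "alcohol", "glycemic_state", "seq_run"] + [
    f"pc{i}" for i in range(1, 11)
]

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "imputation_r2"]


class DataError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class GenotypeMatrix:
    """Samples x variants alternate-allele dosage matrix.

    ``dosage`` holds floats restricted to {0, 1, 2, NaN}; NaN marks a
    missing call. ``variants`` is a DataFrame with columns
    ``chrom, pos, id, ref, alt, imputation_r2`` (``imputation_r2`` NaN for
    directly genotyped variants).
    """

    samples: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise DataError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(set(self.samples)) != len(self.samples):
            raise DataError("duplicate sample ids in genotype matrix")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, [0.0, 1.0, 2.0]).all():
            bad = vals[~np.isin(vals, [0.0, 1.0, 2.0])]
            raise DataError(f"dosages must be 0/1/2/missing; found {bad[:5]}")
        key = self.variants[["chrom", "pos", "alt"]].apply(tuple, axis=1)
        if key.duplicated().any():
            raise DataError("duplicate (chrom, pos, alt) variant records")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            samples=self.samples,
            variants=self.variants.loc[mask].reset_index(drop=True),
            dosage=self.dosage[:, mask],
        )

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return GenotypeMatrix(
            samples=list(sample_ids),
            variants=self.variants,
            dosage=self.dosage[idx, :],
        )


@dataclass
class CountTable:
    """Samples x features integer count table with taxonomy.

    ``counts``: DataFrame (index = sample ids, columns = feature ids) of
    non-negative integers. ``taxonomy``: DataFrame indexed by feature id
    with the seven lineage ranks (empty string = unassigned), a ``rank``
    label ('asv' or a taxonomic rank), and a ``lineage`` string
    ('Bacteria;Firmicutes;...').
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.columns.duplicated().any():
            raise DataError("duplicate feature ids in count table")
        if counts.index.duplicated().any():
            raise DataError("duplicate sample ids in count table")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise DataError("counts must be integers")
            counts = counts.round().astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise DataError("counts must be non-negative")
        self.counts = counts
        missing = set(counts.columns) - set(self.taxonomy.index)
        if missing:
            raise DataError(f"features missing from taxonomy: {sorted(missing)[:5]}")
        self.taxonomy = self.taxonomy.loc[list(counts.columns)]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def features(self) -> list[str]:
        return list(self.counts.columns)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


@dataclass
class CovariateTable:
    """Per-sample design variables (phenotypes, run, genetic PCs)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COVARIATE_COLUMNS if c not in self.data.columns]
        if missing:
            raise DataError(f"covariate table missing columns: {missing}")
        if self.data.index.duplicated().any():
            raise DataError("duplicate sample ids in covariate table")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def complete_samples(self) -> list[str]:
        """Samples with no missing covariate (eligible for model fits)."""
        return list(self.data.index[self.data[COVARIATE_COLUMNS].notna().all(axis=1)])

    def design_matrix(self, samples: list[str] | None = None) -> pd.DataFrame:
        """Model design: intercept, numeric covariates, one-hot categoricals.

        Categorical covariates are dummy-coded with the first observed
        level as reference.
        """
        df = self.data if samples is None else self.data.loc[list(samples)]
        parts = [pd.Series(1.0, index=df.index, name="intercept")]
        for col in COVARIATE_COLUMNS:
            if col in CATEGORICAL_COVARIATES:
                dummies = pd.get_dummies(df[col].astype("category"), prefix=col, drop_first=True)
                parts.append(dummies.astype(float))
            else:
                parts.append(df[col].astype(float))
        return pd.concat(parts, axis=1)


@dataclass
class FeatureSet:
    """Candidate/selected bacterial features with filter and cluster state.

    ``table`` is indexed by feature id with columns ``rank``, ``lineage``,
    ``kept`` (passed the prevalence/median filters), ``cluster`` (int id,
    -1 before clustering), and ``selected`` (cluster representative).
    ``log`` records one row per feature decision (feature, action, reason).
    """

    table: pd.DataFrame
    log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["feature", "action", "reason"])
    )

    @property
    def selected(self) -> pd.DataFrame:
        return self.table[self.table["selected"]]

    @property
    def n_clusters(self) -> int:
        cl = self.table.loc[self.table["cluster"] >= 0, "cluster"]
        return int(cl.nunique())
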