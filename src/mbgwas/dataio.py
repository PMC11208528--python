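"""Readers and writers for the pipeline's external formats.

Genotypes come in as VCF (biallelic SNPs, GT and/or DS fields); counts,
taxonomy, covariates and summary statistics travel as TSV; gene annotation
as BED. Positions are 1-based internally (VCF convention); BED's 0-based
half-open intervals are converted on read.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (
    COVARIATE_COLUMNS,
    RANKS,
    CountTable,
    CovariateTable,
    DataError,
    GenotypeMatrix,
)

logger = logging.getLogger(__name__)

SUMSTATS_COLUMNS = [
    "Chromosome",
    "Position",
    "P",
    "EffectSize",
    "A1",
    "A2",
    "StandardError",
    "rsID",
    "TaxonName",
    "TaxonLevel",
]


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(
    path: str | Path,
    prefer_dosage: bool = False,
    r2_info_key: str = "R2",
) -> GenotypeMatrix:
    """Read a VCF of biallelic SNPs into a dosage matrix.

    Dosage is the alternate-allele count from GT; when ``prefer_dosage``
    is set or GT is absent, the DS field is used, rounded to the nearest
    integer (the association models code genotypes as 0/1/2). Missing
    calls ('./.') become NaN. Imputation quality is taken from the INFO
    key ``r2_info_key`` when present.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    records = []
    columns = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise DataError(
                f"multiallelic record at {var.CHROM}:{var.POS} "
                f"(ALT {','.join(var.ALT)}); only biallelic SNPs are supported"
            )
        try:
            ds = var.format("DS")
        except KeyError:  # DS not declared in the header
            ds = None
        has_gt = var.gt_types is not None and len(var.gt_types) == len(samples)
        use_ds = ds is not None and (prefer_dosage or not _gt_present(var))
        if use_ds:
            dos = np.asarray(ds, dtype=float).reshape(-1)
            dos = np.where(np.isnan(dos), np.nan, np.round(dos))
        elif has_gt and _gt_present(var):
            gt = np.asarray(var.gt_types, dtype=float)  # 0/1/2, 3 = missing
            dos = np.where(gt == 3, np.nan, gt)
        else:
            raise DataError(f"record {var.CHROM}:{var.POS} has neither GT nor DS")
        r2 = var.INFO.get(r2_info_key)
        records.append(
            {
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "id": var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}",
                "ref": var.REF,
                "alt": var.ALT[0],
                "imputation_r2": float(r2) if r2 is not None else np.nan,
            }
        )
        columns.append(dos)
    variants = pd.DataFrame(records, columns=["chrom", "pos", "id", "ref", "alt", "imputation_r2"])
    dosage = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0))
    )
    logger.info("read %d variants x %d samples from %s", len(variants), len(samples), path)
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


def _gt_present(var) -> bool:
    try:
        return var.gt_types is not None and len(var.gt_types) > 0
    except Exception:
        return False


def write_genotypes(G: GenotypeMatrix, path: str | Path) -> None:
    """Write hard-call dosages as a minimal VCF 4.2 with GT (and INFO R2)."""
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(G.samples) + "\n")
        for j, var in G.variants.iterrows():
            info = "." if np.isnan(var["imputation_r2"]) else f"R2={var['imputation_r2']:.4f}"
            calls = [
                "./." if np.isnan(d) else gt_code[d] for d in G.dosage[:, j]
            ]
            fh.write(
                f"{var['chrom']}\t{var['pos']}\t{var['id']}\t{var['ref']}\t{var['alt']}"
                f"\t.\t.\t{info}\tGT\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# counts / taxonomy / covariates


def read_counts(count_path: str | Path, taxonomy_path: str | Path) -> CountTable:
    """Read a sample-by-feature count TSV plus its taxonomy TSV.

    The taxonomy file must carry one row per feature with the seven rank
    columns; a feature present in the counts but absent from the taxonomy
    is an error.
    """
    counts = pd.read_csv(count_path, sep="\t", index_col=0)
    if counts.columns.duplicated().any() or counts.index.duplicated().any():
        raise DataError("duplicate sample or feature ids in count table")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise DataError("non-numeric counts")
    if not np.allclose(arr, np.round(arr)) or (arr < 0).any():
        raise DataError("counts must be non-negative integers")
    counts = counts.astype(np.int64)
    counts.index = counts.index.astype(str)

    tax = pd.read_csv(taxonomy_path, sep="\t", index_col=0, dtype=str).fillna("")
    tax.index = tax.index.astype(str)
    missing_rank_cols = [r for r in RANKS if r not in tax.columns]
    if missing_rank_cols:
        raise DataError(f"taxonomy missing rank columns: {missing_rank_cols}")
    missing = set(counts.columns) - set(tax.index)
    if missing:
        raise DataError(f"no taxonomy for features: {sorted(missing)[:5]}")
    if "rank" not in tax.columns:
        tax["rank"] = "asv"
    if "lineage" not in tax.columns:
        tax["lineage"] = tax[RANKS].apply(
            lambda row: ";".join(v for v in row if v), axis=1
        )
    return CountTable(counts=counts, taxonomy=tax)


def write_counts(table: CountTable, count_path: str | Path, taxonomy_path: str | Path) -> None:
    table.counts.to_csv(count_path, sep="\t")
    table.taxonomy.to_csv(taxonomy_path, sep="\t")


def read_covariates(path: str | Path) -> CovariateTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return CovariateTable(data=df)


def write_covariates(cov: CovariateTable, path: str | Path) -> None:
    cov.data.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# summary statistics


def write_sumstats(assoc: pd.DataFrame, path: str | Path) -> None:
    """Write an association table as a summary-statistics TSV.

    Columns: Chromosome, Position, P, EffectSize, A1, A2, StandardError,
    rsID, TaxonName, TaxonLevel. The effect size is reported for the A2
    (counted = alternate) allele. Floats are written with 12 significant
    digits so that read-back reproduces the values.
    """
    out = assoc[SUMSTATS_COLUMNS].copy()
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_sumstats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"Chromosome": str})
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"summary-statistics file missing columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# gene annotation (BED) and external trait summary stats


def read_gene_bed(path: str | Path) -> pd.DataFrame:
    """Read gene intervals from BED (0-based half-open) to 1-based inclusive."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "name"],
        dtype={"chrom": str},
    )
    df["start"] = df["start"].astype(int) + 1  # to 1-based inclusive
    df["end"] = df["end"].astype(int)
    return df


TRAIT_SUMSTAT_COLUMNS = ["id", "effect_allele", "other_allele", "beta", "se", "p"]


def read_trait_sumstats(path: str | Path) -> pd.DataFrame:
    """Read an external GWAS summary-statistics TSV (normalized schema).

    Required columns: id, effect_allele, other_allele, beta, se, p.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRAIT_SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"trait summary stats missing columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# run configuration


DEFAULT_CONFIG: dict = {
    # feature construction
    "min_prevalence": 100,
    "min_median": 50,
    "spearman_cutoff": 0.985,
    # variant QC
    "maf_min": 0.05,
    "callrate_min": 0.95,
    "hwe_alpha": 0.005,
    "imputation_r2_min": 0.6,  # beta-diversity arm only
    # beta diversity
    "rarefaction_depth": 5000,
    "dbf_moment_permutations": 2000,
    # significance
    "alpha_genome_wide": 5e-8,
    "alpha_study_wide": None,  # default alpha_gw / n_scans; override to pin
    "locus_window_bp": 1_000_000,
    # misc
    "seed": 0,
}


def load_config(path: str | Path | None) -> dict:
    """Load a YAML run configuration, filling unset keys with defaults."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(DEFAULT_CONFIG)
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
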