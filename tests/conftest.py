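import numpy as np
import pandas as pd
import pytest

from mbgwas.containers import RANKS, CountTable, CovariateTable, GenotypeMatrix
from mbgwas.simulate import SimConfig, simulate_cohort


def make_taxonomy(rows: dict[str, list[str]]) -> pd.DataFrame:
    """Taxonomy frame from {feature_id: [kingdom..species]} (short lists padded)."""
    recs = {}
    for fid, lineage in rows.items():
        padded = list(lineage) + [""] * (len(RANKS) - len(lineage))
        recs[fid] = dict(zip(RANKS, padded))
    tax = pd.DataFrame.from_dict(recs, orient="index")
    tax["rank"] = "asv"
    tax["lineage"] = tax[RANKS].apply(lambda r: ";".join(v for v in r if v), axis=1)
    return tax


@pytest.fixture
def toy_counts() -> CountTable:
    """3 samples x 4 ASVs in two genera of one family."""
    counts = pd.DataFrame(
        {
            "ASV1": [3, 10, 0],
            "ASV2": [4, 0, 7],
            "ASV3": [5, 2, 2],
            "ASV4": [0, 1, 9],
        },
        index=["s1", "s2", "s3"],
    )
    tax = make_taxonomy(
        {
            "ASV1": ["Bacteria", "P1", "C1", "O1", "F1", "G1", "Sp1"],
            "ASV2": ["Bacteria", "P1", "C1", "O1", "F1", "G1", "Sp2"],
            "ASV3": ["Bacteria", "P1", "C1", "O1", "F1", "G2", "Sp3"],
            "ASV4": ["Bacteria", "P2", "C2", "O2", "F2", "G3", "Sp4"],
        }
    )
    return CountTable(counts=counts, taxonomy=tax)


@pytest.fixture
def toy_genotypes() -> GenotypeMatrix:
    dosage = np.array(
        [
            [0.0, 2.0, 1.0],
            [1.0, 2.0, 0.0],
            [2.0, np.nan, 1.0],
            [2.0, 2.0, 2.0],
        ]
    )
    variants = pd.DataFrame(
        {
            "chrom": ["1", "1", "2"],
            "pos": [100, 200, 100],
            "id": ["v1", "v2", "v3"],
            "ref": ["A", "C", "G"],
            "alt": ["G", "T", "A"],
            "imputation_r2": [0.9, np.nan, 0.5],
        }
    )
    return GenotypeMatrix(samples=["s1", "s2", "s3", "s4"], variants=variants, dosage=dosage)


@pytest.fixture
def small_cohort():
    """Small but fully realistic synthetic cohort shared across tests."""
    cfg = SimConfig(
        n_samples=200, n_variants=120, n_asv=40, ld_block_size=4, ld_rho=0.5,
        missing_rate=0.01, seed=7,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture
def covariates_200() -> CovariateTable:
    from mbgwas.simulate import simulate_covariates

    return simulate_covariates(SimConfig(n_samples=200, seed=3))
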