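import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mbgwas.beta import (
    GowerMatrix,
    _recentered_subset,
    bray_curtis,
    dbf_test,
    gower_center,
    partial_out_covariates,
    rarefy,
    snp_scan_beta,
)
from mbgwas.containers import CountTable, GenotypeMatrix
from mbgwas.postprocess import genomic_inflation
from conftest import make_taxonomy


def euclid_frame(points: np.ndarray) -> pd.DataFrame:
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    ids = [f"s{i}" for i in range(len(points))]
    return pd.DataFrame(d, index=ids, columns=ids)


class TestRarefy:
    @pytest.fixture
    def counts(self):
        rng = np.random.default_rng(0)
        mat = rng.integers(0, 800, size=(12, 20))
        mat[3] = 0
        mat[3, 0] = 4999  # total 4999 -> dropped at depth 5000
        counts = pd.DataFrame(mat, index=[f"s{i}" for i in range(12)],
                              columns=[f"ASV{j}" for j in range(20)])
        tax = make_taxonomy({f"ASV{j}": ["Bacteria"] for j in range(20)})
        return CountTable(counts=counts, taxonomy=tax)

    def test_retained_totals_exactly_depth(self, counts):
        out = rarefy(counts, depth=5000, seed=1)
        assert (out.counts.sum(axis=1) == 5000).all()

    def test_shallow_sample_dropped(self, counts):
        out = rarefy(counts, depth=5000, seed=1)
        assert "s3" not in out.samples
        assert len(out.samples) == len([
            s for s in counts.samples if counts.counts.loc[s].sum() >= 5000
        ])

    def test_deterministic_and_subsample(self, counts):
        a = rarefy(counts, depth=5000, seed=2)
        b = rarefy(counts, depth=5000, seed=2)
        assert a.counts.equals(b.counts)
        assert (a.counts.to_numpy() <= counts.counts.loc[a.samples].to_numpy()).all()

    def test_bad_depth(self, counts):
        with pytest.raises(ValueError):
            rarefy(counts, depth=0)


class TestBrayCurtis:
    def make(self, rows):
        counts = pd.DataFrame(rows, index=[f"s{i}" for i in range(len(rows))],
                              columns=["a", "b", "c"])
        tax = make_taxonomy({c: ["Bacteria"] for c in ["a", "b", "c"]})
        return CountTable(counts=counts, taxonomy=tax)

    def test_half_overlap_is_half(self):
        D = bray_curtis(self.make([[5, 5, 0], [0, 5, 5]]))
        assert D.iloc[0, 1] == pytest.approx(0.5)

    def test_identity_and_disjoint(self):
        D = bray_curtis(self.make([[3, 1, 0], [3, 1, 0], [0, 0, 9]]))
        assert D.iloc[0, 1] == pytest.approx(0.0)
        assert D.iloc[0, 2] == pytest.approx(1.0)

    def test_all_zero_sample_named(self):
        with pytest.raises(ValueError, match="s1"):
            bray_curtis(self.make([[1, 2, 3], [0, 0, 0]]))


class TestGower:
    def test_two_by_two_hand_value(self):
        D = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["a", "b"], columns=["a", "b"])
        G = gower_center(D)
        np.testing.assert_allclose(G.values, [[0.25, -0.25], [-0.25, 0.25]], atol=1e-12)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(15, 4))
        G = gower_center(euclid_frame(pts))
        assert np.abs(G.values.sum(axis=0)).max() < 1e-8

    def test_euclidean_distances_give_centered_gram(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(10, 3))
        G = gower_center(euclid_frame(pts))
        centered = pts - pts.mean(axis=0)
        np.testing.assert_allclose(G.values, centered @ centered.T, atol=1e-8)


class TestPartialling:
    def test_intercept_only_is_identity(self):
        rng = np.random.default_rng(5)
        G = gower_center(euclid_frame(rng.normal(size=(12, 3))))
        X = pd.DataFrame({"intercept": np.ones(12)})
        G_res = partial_out_covariates(G, X)
        np.testing.assert_allclose(G_res.values, G.values, atol=1e-10)

    def test_partialled_variable_annihilated(self):
        rng = np.random.default_rng(6)
        n = 30
        g = rng.binomial(2, 0.4, n).astype(float)
        pts = np.column_stack([g + rng.normal(scale=0.3, size=n), rng.normal(size=n)])
        G = gower_center(euclid_frame(pts))
        X = pd.DataFrame({"intercept": np.ones(n), "g": g})
        G_res = partial_out_covariates(G, X)
        res = dbf_test(G_res, g + 0.0, seed=0)
        assert res.numerator_trace < 1e-8

    def test_matches_pcoa_then_regress_oracle(self):
        # Euclidean case: partialling the Gower matrix equals regressing
        # the coordinates on the covariates and re-forming the Gram matrix
        rng = np.random.default_rng(7)
        n = 25
        pts = rng.normal(size=(n, 4))
        covs = rng.normal(size=(n, 2))
        X = pd.DataFrame(
            np.column_stack([np.ones(n), covs]), columns=["intercept", "c1", "c2"]
        )
        G_res = partial_out_covariates(gower_center(euclid_frame(pts)), X)
        Xa = X.to_numpy()
        R = np.eye(n) - Xa @ np.linalg.pinv(Xa.T @ Xa) @ Xa.T
        coords = R @ (pts - pts.mean(axis=0))
        np.testing.assert_allclose(G_res.values, coords @ coords.T, atol=1e-6)

    def test_rank_deficient_design_reported(self):
        rng = np.random.default_rng(8)
        n = 10
        G = gower_center(euclid_frame(rng.normal(size=(n, 2))))
        x = rng.normal(size=n)
        X = pd.DataFrame({"intercept": np.ones(n), "a": x, "a_copy": x})
        with pytest.raises(ValueError, match="a_copy"):
            partial_out_covariates(G, X)


class TestDBF:
    def test_equals_classical_regression_f_on_euclidean_line(self):
        rng = np.random.default_rng(9)
        n = 30
        y = rng.normal(size=n)
        g = rng.binomial(2, 0.3, n).astype(float)
        G = gower_center(euclid_frame(y[:, None]))
        res = dbf_test(G, g, seed=1)
        x = g - g.mean()
        yc = y - y.mean()
        b = (x @ yc) / (x @ x)
        rss = ((yc - b * x) ** 2).sum()
        F = ((yc**2).sum() - rss) / (rss / (n - 2))
        assert res.pseudo_F == pytest.approx(F, abs=1e-8)

    def test_invariant_to_affine_rescaling_of_g(self):
        rng = np.random.default_rng(10)
        G = gower_center(euclid_frame(rng.normal(size=(20, 3))))
        g = rng.binomial(2, 0.4, 20).astype(float)
        f0 = dbf_test(G, g, seed=0).pseudo_F
        f1 = dbf_test(G, 5.0 * g - 3.0, seed=0).pseudo_F
        assert f1 == pytest.approx(f0, rel=1e-10)

    def test_invariant_to_joint_relabeling(self):
        rng = np.random.default_rng(11)
        n = 20
        G = gower_center(euclid_frame(rng.normal(size=(n, 3))))
        g = rng.binomial(2, 0.4, n).astype(float)
        perm = rng.permutation(n)
        Gp = GowerMatrix(values=G.values[np.ix_(perm, perm)],
                         samples=[G.samples[i] for i in perm],
                         n_covariates=G.n_covariates)
        f0 = dbf_test(G, g, seed=0).pseudo_F
        f1 = dbf_test(Gp, g[perm], seed=0).pseudo_F
        assert f1 == pytest.approx(f0, rel=1e-10)

    def test_monomorphic_and_df_errors(self):
        rng = np.random.default_rng(12)
        G = gower_center(euclid_frame(rng.normal(size=(5, 2))))
        with pytest.raises(ValueError, match="monomorphic"):
            dbf_test(G, np.ones(5))
        G.n_covariates = 4
        with pytest.raises(ValueError, match="denominator df"):
            dbf_test(G, rng.binomial(2, 0.4, 5).astype(float))

    def test_permutation_p_uniform_under_null(self):
        # exchangeable validity of the permutation p on its achievable grid
        rng = np.random.default_rng(13)
        n = 25
        ps = []
        for _ in range(200):
            G = gower_center(euclid_frame(rng.normal(size=(n, 3))))
            g = rng.binomial(2, 0.3, n).astype(float)
            ps.append(dbf_test(G, g, n_perm=199, seed=int(rng.integers(1 << 30))).p_perm)
        ps = np.array(ps)
        # super-uniformity at a few fixed levels (discrete grid)
        for alpha in (0.05, 0.1, 0.25):
            assert (ps <= alpha).mean() <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / 200)


class TestBetaScan:
    def _genotypes(self, dosage, r2=None):
        n, m = dosage.shape
        variants = pd.DataFrame(
            {"chrom": "1", "pos": np.arange(m) * 1000 + 1,
             "id": [f"v{j}" for j in range(m)], "ref": "A", "alt": "G",
             "imputation_r2": r2 if r2 is not None else np.nan}
        )
        return GenotypeMatrix(samples=[f"s{i}" for i in range(n)],
                              variants=variants, dosage=dosage)

    def test_r2_filtered_variant_absent_but_reported(self):
        rng = np.random.default_rng(14)
        n = 40
        dosage = rng.binomial(2, 0.4, size=(n, 3)).astype(float)
        G = self._genotypes(dosage, r2=[0.9, 0.5, 0.95])
        from mbgwas.abundance import variant_qc

        keep, report = variant_qc(G, r2_min=0.6)
        assert not keep[1] and report.loc[1, "drop_reason"] == "imputation_r2"
        pts = rng.normal(size=(n, 3))
        Gw = gower_center(euclid_frame(pts))
        out = snp_scan_beta(Gw, G, keep_mask=keep, n_moment_perm=1000, seed=0)
        assert "v1" not in set(out["rsID"])
        assert len(out) == 2

    def test_missing_genotypes_recentred_subset(self):
        rng = np.random.default_rng(15)
        n = 30
        dosage = rng.binomial(2, 0.4, size=(n, 1)).astype(float)
        dosage[:4, 0] = np.nan
        G = self._genotypes(dosage)
        Gw = gower_center(euclid_frame(rng.normal(size=(n, 3))))
        out = snp_scan_beta(Gw, G, n_moment_perm=1000, seed=0)
        assert out.loc[0, "n"] == n - 4
        # equals a direct test on the complete subset
        mask = ~np.isnan(dosage[:, 0])
        sub = _recentered_subset(Gw, mask)
        direct = dbf_test(sub, dosage[mask, 0], n_moment_perm=1000, seed=0)
        assert out.loc[0, "pseudo_F"] == pytest.approx(direct.pseudo_F, rel=1e-10)

    def test_planted_compositional_variant_is_top_hit(self):
        # community composition keyed to dosage: the planted variant is the
        # minimum p among 300 variants in >= 80% of 20 seeds
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(3000 + seed)
            n, m = 120, 300
            dosage = rng.binomial(2, 0.3, size=(n, m)).astype(float)
            planted = 150
            base = rng.gamma(2.0, 50, size=(n, 25))
            shift = np.zeros((n, 25))
            shift[:, :5] = dosage[:, [planted]] * base[:, :5] * 0.4
            comp = base + shift
            D = pd.DataFrame(
                np.abs(comp[:, None, :] - comp[None, :, :]).sum(-1)
                / (comp[:, None, :] + comp[None, :, :]).sum(-1),
                index=[f"s{i}" for i in range(n)], columns=[f"s{i}" for i in range(n)],
            )
            Gw = gower_center(D)
            G = self._genotypes(dosage)
            out = snp_scan_beta(Gw, G, n_moment_perm=1000, seed=seed)
            if out.loc[out["P"].idxmin(), "rsID"] == f"v{planted}":
                wins += 1
        assert wins >= 16

    def test_null_scan_lambda_calibrated(self):
        # enough variants that the median-based lambda estimate is stable
        rng = np.random.default_rng(16)
        n, m = 100, 2000
        dosage = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        G = self._genotypes(dosage)
        comp = rng.gamma(1.0, 100, size=(n, 30))
        D = pd.DataFrame(
            np.abs(comp[:, None, :] - comp[None, :, :]).sum(-1)
            / (comp[:, None, :] + comp[None, :, :]).sum(-1),
            index=[f"s{i}" for i in range(n)], columns=[f"s{i}" for i in range(n)],
        )
        out = snp_scan_beta(gower_center(D), G, n_moment_perm=1000, seed=1)
        lam = genomic_inflation(out["P"].to_numpy())
        assert 0.9 <= lam <= 1.1


from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays


@settings(derandomize=True, max_examples=30)
@given(
    arrays(np.int64, shape=(4, 6), elements=st.integers(min_value=0, max_value=500))
)
def test_bray_curtis_bounds_and_symmetry(mat):
    if (mat.sum(axis=1) == 0).any():
        return  # undefined for empty samples, covered by the error test
    counts = pd.DataFrame(mat, index=[f"s{i}" for i in range(4)],
                          columns=[f"t{j}" for j in range(6)])
    tax = make_taxonomy({f"t{j}": ["Bacteria"] for j in range(6)})
    D = bray_curtis(CountTable(counts=counts, taxonomy=tax))
    v = D.to_numpy()
    assert np.allclose(v, v.T, atol=1e-12)
    assert np.allclose(np.diag(v), 0.0)
    assert (v >= -1e-12).all() and (v <= 1 + 1e-12).all()


@settings(derandomize=True, max_examples=20)
@given(st.integers(min_value=5, max_value=25))
def test_gower_rows_always_centered(n):
    rng = np.random.default_rng(n)
    pts = rng.normal(size=(n, 3))
    G = gower_center(euclid_frame(pts))
    assert np.abs(G.values.sum(axis=0)).max() < 1e-8
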