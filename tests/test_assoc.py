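import numpy as np
import pytest
from scipy import stats

from embgwas import assoc, synthcohort
from embgwas.embedding import CovariateMatrix

from conftest import random_covariates


def brute_force_gls(Y, Cv, g):
    """Independent oracle: explicit projector and matrix inverses."""
    n = Y.shape[0]
    M = np.eye(n) - Cv @ np.linalg.inv(Cv.T @ Cv) @ Cv.T
    den = g @ M @ g
    beta = (g @ M @ Y) / den
    E = M @ Y
    sigma = E.T @ E / (n - Cv.shape[1])
    lam = den * beta @ np.linalg.inv(sigma) @ beta
    return beta, lam


class TestFitNull:
    def test_exact_fit_triggers_non_pd_error(self):
        rng = np.random.default_rng(0)
        n = 30
        C = random_covariates(n, 2, seed=1)
        B = rng.standard_normal((3, 2))
        Y = C.values @ B  # lies exactly in the covariate span
        with pytest.raises(ValueError, match="positive definite"):
            assoc.fit_null(Y, C)

    def test_k1_matches_ols_residual_variance(self):
        # tiny instance with printed numbers
        y = np.array([1.0, 2.0, 2.5, 3.9, 5.1, 5.9, 7.2, 8.1, 8.8, 10.2])
        x = np.arange(10, dtype=float)
        C = CovariateMatrix(
            sample_ids=[f"s{i}" for i in range(10)],
            values=np.column_stack([np.ones(10), x]),
            columns=["intercept", "x"],
        )
        null = assoc.fit_null(y[:, None], C)
        beta, res, *_ = np.linalg.lstsq(C.values, y, rcond=None)
        resid = y - C.values @ beta
        np.testing.assert_allclose(null.sigma[0, 0], resid @ resid / 8, rtol=1e-12)

    def test_large_sample_identity_covariance(self):
        rng = np.random.default_rng(2)
        n, k = 5000, 5
        Y = rng.standard_normal((n, k))
        C = CovariateMatrix(
            sample_ids=[f"s{i}" for i in range(n)],
            values=np.ones((n, 1)),
            columns=["intercept"],
        )
        null = assoc.fit_null(Y, C)
        assert np.abs(null.sigma - np.eye(k)).max() < 0.08

    def test_insufficient_dof_rejected(self):
        rng = np.random.default_rng(3)
        Y = rng.standard_normal((5, 4))
        with pytest.raises(ValueError, match="degrees of freedom"):
            assoc.fit_null(Y, random_covariates(5, 1, seed=4))


class TestScoreTest:
    def test_orthogonal_g_gives_null_record(self):
        rng = np.random.default_rng(5)
        n, k = 40, 3
        C = random_covariates(n, 1, seed=6)
        Y = rng.standard_normal((n, k))
        null = assoc.fit_null(Y, C)
        # construct g orthogonal to M-residualized Y (and not in span of C)
        resid = null.residuals
        q, _ = np.linalg.qr(np.column_stack([C.values, resid]))
        g = rng.standard_normal(n)
        g -= q @ (q.T @ g)
        rec = assoc.test_score(null, g)
        assert np.abs(rec.beta).max() < 1e-10
        assert rec.statistic < 1e-18
        assert rec.p_value == pytest.approx(1.0)

    def test_k1_equals_classical_score_statistic(self):
        rng = np.random.default_rng(7)
        n = 60
        C = random_covariates(n, 2, seed=8)
        y = rng.standard_normal((n, 1))
        g = rng.integers(0, 3, n).astype(float)
        null = assoc.fit_null(y, C)
        rec = assoc.test_score(null, g)
        Cv = C.values
        M = np.eye(n) - Cv @ np.linalg.inv(Cv.T @ Cv) @ Cv.T
        sigma0 = (y[:, 0] @ M @ y[:, 0]) / (n - Cv.shape[1])
        oracle = (g @ M @ y[:, 0]) ** 2 / ((g @ M @ g) * sigma0)
        assert abs(rec.statistic - oracle) < 1e-10

    def test_small_instance_brute_force_gls(self):
        rng = np.random.default_rng(9)
        n, k = 8, 2
        C = random_covariates(n, 1, seed=10)
        Y = rng.standard_normal((n, k))
        g = rng.integers(0, 3, n).astype(float)
        null = assoc.fit_null(Y, C)
        rec = assoc.test_score(null, g)
        beta, lam = brute_force_gls(Y, C.values, g)
        np.testing.assert_allclose(rec.beta, beta, rtol=1e-10)
        assert abs(rec.statistic - lam) <= 1e-8 * max(1.0, lam)

    def test_monomorphic_flagged(self):
        rng = np.random.default_rng(11)
        n = 30
        C = random_covariates(n, 1, seed=12)
        Y = rng.standard_normal((n, 2))
        null = assoc.fit_null(Y, C)
        rec = assoc.test_score(null, np.ones(n))
        assert rec.flag == "monomorphic/collinear"
        assert np.isnan(rec.p_value)

    def test_scale_invariance_in_g(self):
        rng = np.random.default_rng(13)
        n = 50
        C = random_covariates(n, 1, seed=14)
        Y = rng.standard_normal((n, 3))
        g = rng.integers(0, 3, n).astype(float)
        null = assoc.fit_null(Y, C)
        a = assoc.test_score(null, g)
        b = assoc.test_score(null, 7.3 * g)
        assert abs(a.statistic - b.statistic) < 1e-9

    def test_invariance_to_phenotype_remixing(self):
        rng = np.random.default_rng(15)
        n, k = 80, 4
        C = random_covariates(n, 2, seed=16)
        Y = rng.standard_normal((n, k))
        g = rng.integers(0, 3, n).astype(float)
        lam0 = assoc.test_score(assoc.fit_null(Y, C), g).statistic
        for trial in range(5):
            A = rng.standard_normal((k, k))
            while abs(np.linalg.det(A)) < 1e-3:
                A = rng.standard_normal((k, k))
            lam = assoc.test_score(assoc.fit_null(Y @ A, C), g).statistic
            assert abs(lam - lam0) < 1e-8 * max(1.0, lam0)

    def test_mean_imputation_of_missing(self):
        rng = np.random.default_rng(17)
        n = 40
        C = random_covariates(n, 1, seed=18)
        Y = rng.standard_normal((n, 2))
        g = rng.integers(0, 3, n).astype(float)
        gm = g.copy()
        gm[:5] = np.nan
        filled = g.copy()
        filled[:5] = g[5:].mean()
        null = assoc.fit_null(Y, C)
        a = assoc.test_score(null, gm)
        b = assoc.test_score(null, filled)
        assert abs(a.statistic - b.statistic) < 1e-12
        assert a.callrate == pytest.approx(35 / 40)


class TestRefined:
    def test_n_iter_zero_reduces_to_score(self):
        rng = np.random.default_rng(19)
        n = 30
        C = random_covariates(n, 1, seed=20)
        Y = rng.standard_normal((n, 3))
        g = rng.integers(0, 3, n).astype(float)
        null = assoc.fit_null(Y, C)
        a = assoc.test_score(null, g)
        b = assoc.test_refined(null, g, n_iter=0)
        assert a.statistic == b.statistic and a.p_value == b.p_value

    def test_refined_calibrated_under_null(self):
        rng = np.random.default_rng(21)
        n, k, v = 2000, 5, 400
        C = random_covariates(n, 2, seed=22)
        Y = rng.standard_normal((n, k))
        null = assoc.fit_null(Y, C)
        G = rng.binomial(2, 0.3, size=(n, v)).astype(float)
        ps = np.array(
            [assoc.test_refined(null, G[:, j]).p_value for j in range(v)]
        )
        rate = (ps < 0.05).mean()
        band = 3 * np.sqrt(0.05 * 0.95 / v)
        assert abs(rate - 0.05) < band

    def test_refined_agrees_with_score_for_strong_effect(self):
        rng = np.random.default_rng(23)
        n, k = 1500, 4
        C = random_covariates(n, 1, seed=24)
        g = rng.binomial(2, 0.4, n).astype(float)
        Y = rng.standard_normal((n, k))
        Y[:, 0] += 0.4 * (g - g.mean())
        null = assoc.fit_null(Y, C)
        a = assoc.test_score(null, g)
        b = assoc.test_refined(null, g)
        assert a.p_value < 1e-8 and b.p_value < 1e-8
        np.testing.assert_allclose(a.beta, b.beta, rtol=1e-12)


class TestRunGwas:
    def test_maf_filter_error_when_empty(self, small_cohort, null_phenotypes):
        _, genotypes, _, _ = small_cohort
        Y, C = null_phenotypes
        with pytest.raises(ValueError, match="MAF"):
            assoc.run_gwas(genotypes, Y, C, maf_min=0.49999)

    def test_null_lambda_gc_near_one(self):
        cfg = synthcohort.SyntheticConfig(
            n_participants=500,
            n_variants=2000,
            n_causal_variants=0,
            n_raw_features=8,
            seed=77,
            ld_decay=0.2,
        )
        g = synthcohort.simulate_genotypes(cfg)
        from embgwas import embedding

        feats, truth = synthcohort.simulate_cohort(cfg, g)
        avg = embedding.average_eyes(feats)
        _, emb = embedding.fit_pca(avg, n_components=8)
        Y = embedding.rank_inverse_normal(emb.values)
        C = embedding.build_covariates(avg.sample_ids, truth.age_vector, truth.sex_vector)
        records = assoc.run_gwas(g, Y, C, maf_min=0.01)
        assert 0.95 <= assoc.genomic_inflation(records) <= 1.05

    def test_planted_dense_variant_is_top_hit(self, small_cohort, null_phenotypes):
        _, genotypes, _, truth = small_cohort
        Y, C = null_phenotypes
        records = assoc.run_gwas(genotypes, Y, C, maf_min=0.01)
        best = min(records, key=lambda r: r.p_value)
        assert best.variant_id in set(truth.causal_variant_ids)

    def test_k1_multivariate_equals_univariate_path(self):
        rng = np.random.default_rng(25)
        cfg = synthcohort.SyntheticConfig(
            n_participants=300,
            n_variants=50,
            n_causal_variants=0,
            n_raw_features=4,
            effect_dims=2,
            seed=31,
        )
        g = synthcohort.simulate_genotypes(cfg)
        C = random_covariates(300, 1, seed=26)
        Y = rng.standard_normal((300, 1))
        records = assoc.run_gwas(g, Y, C, maf_min=0.01)
        uni = assoc.test_univariate_acat(g, Y, C, maf_min=0.01)
        for rec, p_uni in zip(records, uni["P_ACAT"]):
            assert abs(rec.p_value - p_uni) < 1e-10


class TestAcat:
    def test_all_half_combines_to_half(self):
        assert assoc.acat_combine(np.full(5, 0.5)) == pytest.approx(0.5, abs=1e-14)

    def test_k1_identity(self):
        for p in [0.001, 0.2, 0.77]:
            assert abs(assoc.acat_combine(np.array([p])) - p) < 1e-12

    def test_fixed_triple_against_oracle(self):
        import math

        p = np.array([0.01, 0.2, 0.9])
        t = sum(math.tan((0.5 - x) * math.pi) for x in p) / 3
        oracle = 0.5 - math.atan(t) / math.pi
        assert abs(assoc.acat_combine(p) - oracle) < 1e-12

    def test_degenerate_p_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            out = assoc.acat_combine(np.array([0.0, 0.5]))
        assert 0 < out < 1

    def test_null_uniformity(self):
        rng = np.random.default_rng(27)
        combined = [
            assoc.acat_combine(rng.uniform(size=5)) for _ in range(10_000)
        ]
        ks = stats.kstest(combined, "uniform")
        assert ks.pvalue > 0.01


class TestPermutationNull:
    def test_identity_permutation_reproduces_unpermuted(self, small_cohort, null_phenotypes):
        _, genotypes, _, _ = small_cohort
        Y, C = null_phenotypes
        n = Y.shape[0]
        rep = assoc.permutation_null(
            genotypes, Y, C, n_perm=1, seed=0, permutations=[np.arange(n)]
        )
        records = assoc.run_gwas(genotypes, Y, C, maf_min=0.0)
        direct = np.array([r.statistic for r in records])
        np.testing.assert_allclose(np.sort(rep.statistics), np.sort(direct), rtol=1e-9)

    def test_calibration(self, small_cohort, null_phenotypes):
        _, genotypes, _, _ = small_cohort
        Y, C = null_phenotypes
        rep = assoc.permutation_null(genotypes, Y, C, n_perm=50, seed=3)
        assert rep.ks_p_value > 0.01
        n_stats = rep.statistics.size
        band = 2 * np.sqrt(0.05 * 0.95 / n_stats)
        assert abs(rep.empirical_alpha[1] - 0.05) < band + 0.01


class TestBurden:
    def test_burden_equals_variant_test(self, small_cohort, null_phenotypes):
        _, genotypes, _, _ = small_cohort
        Y, C = null_phenotypes
        g = genotypes.dosages[:, 10]
        null = assoc.fit_null(Y, C)
        variant_rec = assoc.test_score(null, g)
        burden_rec = assoc.test_burden(g[None, :], Y, C, gene_ids=["g1"])[0]
        assert burden_rec.statistic == pytest.approx(variant_rec.statistic, rel=1e-12)

    def test_constant_burden_flagged(self, null_phenotypes):
        Y, C = null_phenotypes
        rec = assoc.test_burden(np.ones((1, Y.shape[0])), Y, C)[0]
        assert rec.flag and np.isnan(rec.p_value)

    def test_null_burden_uniform(self):
        rng = np.random.default_rng(28)
        n, k = 400, 3
        C = random_covariates(n, 1, seed=29)
        Y = rng.standard_normal((n, k))
        B = rng.standard_normal((2000, n))
        recs = assoc.test_burden(B, Y, C)
        ps = np.array([r.p_value for r in recs])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_burden_association(self):
        rng = np.random.default_rng(30)
        n, k = 800, 3
        C = random_covariates(n, 1, seed=31)
        Y = rng.standard_normal((n, k))
        b = Y[:, 0] + 0.3 * rng.standard_normal(n)
        rec = assoc.test_burden(b[None, :], Y, C)[0]
        assert rec.p_value < 1e-8
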