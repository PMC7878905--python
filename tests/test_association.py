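"""Null model, burden and SKAT score tests, quadratic-form p-values."""

import numpy as np
import pytest
from scipy import stats

from uromet.association import (
    BETA_1_25,
    FLAT,
    burden_test,
    conditional_reanalysis,
    effect_proportion,
    fit_null_model,
    quadform_pvalue,
    single_variant_tests,
    skat_test,
)


def _random_instance(rng, n=60, m=3, p_cov=3):
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p_cov))])
    G = rng.binomial(2, 0.1, (n, m)).astype(float)
    y = rng.standard_normal(n) + 0.3 * G.sum(axis=1)
    return y, X, G


class TestNullModel:
    def test_intercept_only_hand_arithmetic(self):
        null = fit_null_model(np.array([1.0, 2.0, 3.0]), np.ones((3, 1)))
        np.testing.assert_allclose(null.residuals, [-1.0, 0.0, 1.0])
        assert null.sigma2 == pytest.approx(1.0)

    def test_singular_design_raises(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.column_stack([np.ones(4), y, 2 * y])  # aliased columns
        with pytest.raises(ValueError, match="singular"):
            fit_null_model(y, X)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(0)
        y, X, _ = _random_instance(rng)
        null = fit_null_model(y, X)
        assert np.abs(X.T @ null.residuals).max() < 1e-9

    def test_complete_case_dropping_recorded(self):
        y = np.array([1.0, np.nan, 3.0, 4.0, 2.0])
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        X[3, 1] = np.nan
        null = fit_null_model(y, X)
        assert null.n == 3 and null.n_dropped == 2


class TestBurden:
    def test_single_variant_equals_burden_flat(self):
        rng = np.random.default_rng(1)
        y, X, G = _random_instance(rng, m=1)
        null = fit_null_model(y, X)
        b, se, p = burden_test(null, G, FLAT)
        sv = single_variant_tests(null, G)
        assert b == pytest.approx(sv["beta"][0], abs=1e-10)
        assert p == pytest.approx(sv["p"][0], abs=1e-10)

    def test_matches_ols_refit_oracle(self):
        # joint least-squares refit of y on (X, s) via statsmodels, 100 instances
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        for _ in range(100):
            m = rng.integers(1, 5)
            y, X, G = _random_instance(rng, n=int(rng.integers(30, 80)), m=int(m))
            w = rng.uniform(0.5, 2.0, m)
            null = fit_null_model(y, X)
            b, se, _ = burden_test(null, G, w)
            fit = sm.OLS(y, np.column_stack([X, G @ w])).fit()
            assert b == pytest.approx(fit.params[-1], rel=1e-8)
            # score-test SE uses the null residual variance; rescale the OLS SE
            se_null_scale = fit.bse[-1] * np.sqrt(null.sigma2 / fit.scale)
            assert se == pytest.approx(se_null_scale, rel=1e-8)

    def test_small_fixed_dataset_normal_equations(self):
        # n=8, 2 variants, printed fixture; oracle = normal equations by hand
        y = np.array([0.2, 1.1, -0.3, 2.0, 0.7, -0.5, 1.4, 0.9])
        X = np.column_stack([np.ones(8), [52, 60, 47, 71, 55, 63, 58, 49.0]])
        G = np.array(
            [[0, 0], [1, 0], [0, 0], [1, 1], [0, 1], [0, 0], [1, 0], [0, 0.0]]
        )
        null = fit_null_model(y, X)
        b, _, _ = burden_test(null, G, FLAT)
        Z = np.column_stack([X, G.sum(axis=1)])
        beta_joint = np.linalg.solve(Z.T @ Z, Z.T @ y)
        assert b == pytest.approx(beta_joint[-1], rel=1e-10)

    def test_constant_score_raises(self):
        rng = np.random.default_rng(3)
        y, X, _ = _random_instance(rng)
        null = fit_null_model(y, X)
        with pytest.raises(ValueError, match="constant"):
            burden_test(null, np.ones((null.n, 1)), FLAT)


class TestSkat:
    def test_single_variant_reduces_to_chi2_score_test(self):
        rng = np.random.default_rng(4)
        y, X, G = _random_instance(rng, m=1)
        null = fit_null_model(y, X)
        q, p_skat, fallback = skat_test(null, G, FLAT)
        b, se, _ = burden_test(null, G, FLAT)
        p_chi2 = stats.chi2.sf((b / se) ** 2, 1)
        assert not fallback
        assert p_skat == pytest.approx(p_chi2, abs=1e-8)

    def test_skat_beats_burden_with_opposing_effects(self):
        # two variants with equal and opposite effects: burden score cancels
        rng = np.random.default_rng(5)
        n, reps, alpha = 400, 150, 0.05
        hits_skat = hits_burden = 0
        G = rng.binomial(2, 0.05, (n, 2)).astype(float)
        X = np.ones((n, 1))
        for _ in range(reps):
            y = rng.standard_normal(n) + 0.8 * G[:, 0] - 0.8 * G[:, 1]
            null = fit_null_model(y, X)
            _, _, p_b = burden_test(null, G, FLAT)
            _, p_s, _ = skat_test(null, G, FLAT)
            hits_burden += p_b < alpha
            hits_skat += p_s < alpha
        assert hits_skat > hits_burden

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(6)
        n = 300
        G = rng.binomial(2, 0.02, (n, 5)).astype(float)
        X = np.ones((n, 1))
        ps, pb = [], []
        for _ in range(400):
            y = rng.standard_normal(n)
            null = fit_null_model(y, X)
            _, p_s, _ = skat_test(null, G, BETA_1_25, G.mean(axis=0) / 2)
            _, _, p_b = burden_test(null, G, FLAT)
            ps.append(p_s)
            pb.append(p_b)
        assert stats.kstest(ps, "uniform").pvalue > 0.01
        assert stats.kstest(pb, "uniform").pvalue > 0.01


class TestQuadformPvalue:
    def test_chi2_1_survival_oracle(self):
        p, fallback = quadform_pvalue(3.841459, [1.0])
        assert not fallback
        assert p == pytest.approx(0.05, abs=1e-6)
        for q in (0.5, 2.0, 7.0, 15.0):
            p, _ = quadform_pvalue(q, [1.0])
            assert p == pytest.approx(stats.chi2.sf(q, 1), abs=1e-8)

    def test_equal_lambdas_match_chi2_2(self):
        for q in (0.3, 1.0, 4.0, 9.0, 18.0):
            p, fallback = quadform_pvalue(q, [1.0, 1.0])
            assert not fallback
            assert p == pytest.approx(stats.chi2.sf(q, 2), abs=1e-8)

    def test_matches_monte_carlo_tail(self):
        rng = np.random.default_rng(7)
        draws = 2.0 * rng.chisquare(1, 10**6) + rng.chisquare(1, 10**6)
        for q in (2.0, 5.0, 10.0, 16.0):
            p, _ = quadform_pvalue(q, [2.0, 1.0])
            emp = (draws > q).mean()
            se = np.sqrt(emp * (1 - emp) / 10**6)
            assert abs(p - emp) < 3 * se

    def test_far_tail_uses_flagged_fallback(self):
        p, fallback = quadform_pvalue(200.0, [1.0])
        assert fallback
        assert p == pytest.approx(stats.chi2.sf(200.0, 1), rel=0.2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            quadform_pvalue(np.nan, [1.0])
        with pytest.raises(ValueError):
            quadform_pvalue(1.0, [])
        assert quadform_pvalue(0.0, [1.0]) == (1.0, False)


class TestSingleVariant:
    def test_exact_linear_relationship(self):
        rng = np.random.default_rng(8)
        n = 50
        g = rng.binomial(2, 0.3, n).astype(float)
        y = 1.5 * g + 2.0
        null = fit_null_model(y, np.ones((n, 1)))
        res = single_variant_tests(null, g[:, None])
        assert res["beta"][0] == pytest.approx(1.5, rel=1e-10)
        # score test keeps the null residual variance (which contains the
        # genetic signal), so p is extreme but does not fully underflow
        assert res["p"][0] < 1e-10

    def test_permuted_genotypes_give_uniform_p(self):
        rng = np.random.default_rng(9)
        n = 200
        g = rng.binomial(2, 0.1, n).astype(float)
        y = rng.standard_normal(n) + 0.5 * g
        ps = []
        for _ in range(300):
            null = fit_null_model(y, np.ones((n, 1)))
            ps.append(single_variant_tests(null, rng.permutation(g)[:, None])["p"][0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestConditional:
    def test_independent_index_snp_keeps_effect(self):
        rng = np.random.default_rng(10)
        n = 3000
        G = rng.binomial(2, 0.005, (n, 4)).astype(float)
        idx = rng.binomial(2, 0.3, n).astype(float)  # unlinked common SNP
        X = np.ones((n, 1))
        y = rng.standard_normal(n) + 0.7 * G.sum(axis=1)
        out = conditional_reanalysis(y, X, G, idx)
        assert 85 <= out["effect_proportion_pct"] <= 115

    def test_index_equal_to_burden_abolishes_signal(self):
        rng = np.random.default_rng(11)
        n = 3000
        G = rng.binomial(2, 0.005, (n, 4)).astype(float)
        X = np.ones((n, 1))
        y = rng.standard_normal(n) + 0.7 * G.sum(axis=1)
        out = conditional_reanalysis(y, X, G, G.sum(axis=1))
        assert abs(out["effect_proportion_pct"]) <= 10
        assert out["conditional"]["p_burden"] > 0.01

    def test_collinear_index_rejected(self):
        n = 100
        X = np.column_stack([np.ones(n), np.arange(n, dtype=float)])
        y = np.arange(n, dtype=float) + 1.0
        G = np.zeros((n, 1))
        G[:5] = 1.0
        with pytest.raises(ValueError, match="singular"):
            conditional_reanalysis(y, X, G, X[:, 1])


class TestEffectProportion:
    @pytest.mark.parametrize(
        "cond,uncond,expected", [(0.98, 0.92, 107), (0.75, 0.76, 99), (0.5, 0.5, 100)]
    )
    def test_integer_percent(self, cond, uncond, expected):
        assert effect_proportion(cond, uncond) == expected

    def test_zero_unconditional_raises_and_sign_flip_warns(self):
        with pytest.raises(ValueError):
            effect_proportion(0.5, 0.0)
        with pytest.warns(UserWarning):
            effect_proportion(-0.1, 0.5)


def test_noise_variant_shrinks_burden_toward_null_predictably():
    # adding an independent null variant dilutes the burden slope by the MAC
    # ratio; the simulated mean shift must match that prediction within 3 SE
    rng = np.random.default_rng(12)
    n, reps = 2000, 120
    G = rng.binomial(2, 0.005, (n, 4)).astype(float)
    noise = rng.binomial(2, 0.002, n).astype(float)
    X = np.ones((n, 1))
    mac_signal, mac_noise = G.sum(), noise.sum()
    predicted = 0.7 * mac_signal / (mac_signal + mac_noise)
    deltas = []
    for _ in range(reps):
        y = rng.standard_normal(n) + 0.7 * G.sum(axis=1)
        null = fit_null_model(y, X)
        b_plain, _, _ = burden_test(null, G, FLAT)
        b_noise, _, _ = burden_test(null, np.column_stack([G, noise]), FLAT)
        deltas.append(b_noise - b_plain)
    mean_delta = np.mean(deltas)
    se = np.std(deltas, ddof=1) / np.sqrt(reps)
    assert abs(mean_delta - (predicted - 0.7)) < 3 * se + 0.02
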