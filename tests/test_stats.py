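"""Enrichment, bootstrap, permutation and regression integration statistics."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from pleioscan import stats


class TestFisherEnrichment:
    def test_matches_hypergeometric_enumeration(self):
        # 2x2 table [[10, 90], [5, 895]]
        a = np.zeros(1000, bool); a[:100] = True
        b = np.zeros(1000, bool); b[:10] = True; b[100:105] = True
        res = stats.fisher_enrichment(a, b)
        # two-sided Fisher p by enumerating tables at fixed margins
        N, K, n = 1000, 15, 100   # total, b-margin, a-margin
        def p_tab(k):
            return comb(K, k) * comb(N - K, n - k) / comb(N, n)
        obs = p_tab(10)
        p = sum(p_tab(k) for k in range(0, min(K, n) + 1)
                if p_tab(k) <= obs * (1 + 1e-9))
        assert res["p"] == pytest.approx(p, rel=1e-6)
        assert res["odds_ratio"] > 1

    def test_null_or_near_one(self):
        rng = np.random.default_rng(0)
        covered = 0
        for _ in range(20):
            a = rng.random(500) < 0.2
            b = rng.random(500) < 0.1
            res = stats.fisher_enrichment(a, b)
            covered += res["p"] > 0.05
        assert covered >= 16

    def test_complete_containment_infinite_or(self):
        a = np.zeros(100, bool); a[:10] = True
        b = a.copy()
        res = stats.fisher_enrichment(a, b)
        assert np.isinf(res["odds_ratio"])


class TestBootstrapCi:
    def test_degenerate_all_ones(self):
        res = stats.bootstrap_percent_ci(np.ones(50), B=200, seed=1)
        assert (res["percent"], res["lo"], res["hi"]) == (100.0, 100.0, 100.0)

    def test_width_matches_binomial(self):
        rng = np.random.default_rng(2)
        flags = rng.random(1000) < 0.3
        res = stats.bootstrap_percent_ci(flags, B=2000, seed=3)
        expect = 2 * 1.96 * np.sqrt(0.3 * 0.7 / 1000) * 100
        assert res["hi"] - res["lo"] == pytest.approx(expect, rel=0.30)

    def test_seed_determinism(self):
        flags = np.random.default_rng(4).random(100) < 0.5
        a = stats.bootstrap_percent_ci(flags, seed=9)
        b = stats.bootstrap_percent_ci(flags, seed=9)
        assert a == b


class TestPermutationFitTest:
    def test_maximal_separation_min_p(self):
        rng = np.random.default_rng(5)
        labels = np.r_[np.ones(20), np.zeros(80)]
        stat = labels * 1.0
        S = rng.integers(1, 30, 100).astype(float)
        res = stats.permutation_fit_test(stat, S, labels, n_perm=999, seed=0)
        assert res.p == pytest.approx(1 / 1000)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            stats.permutation_fit_test(np.random.default_rng(0).normal(size=20),
                                       np.arange(20), np.ones(20), 100, 0)

    def test_null_type_one_error(self):
        """Empirical alpha at 0.05 within [0.03, 0.07] under exchangeability."""
        rng = np.random.default_rng(6)
        rejections = 0
        runs = 250
        for i in range(runs):
            stat = rng.normal(size=60)
            S = rng.integers(1, 20, 60).astype(float)
            labels = np.zeros(60); labels[:12] = 1
            rng.shuffle(labels)
            res = stats.permutation_fit_test(stat, S, labels,
                                             n_perm=199, seed=1000 + i)
            rejections += res.p <= 0.05
        assert 0.03 <= rejections / runs <= 0.07

    def test_observed_fit_matches_ols(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(7)
        stat = rng.normal(size=50)
        S = rng.integers(1, 20, 50).astype(float)
        labels = (rng.random(50) < 0.3).astype(float)
        res = stats.permutation_fit_test(stat, S, labels, n_perm=10, seed=0)
        X = sm.add_constant(np.column_stack([S, labels]))
        want = sm.OLS(stat, X).fit().rsquared
        assert res.observed_fit == pytest.approx(want, rel=1e-9)


class TestRegressions:
    def test_connectivity_slope_recovered(self):
        rng = np.random.default_rng(8)
        k = rng.normal(size=400)
        level = rng.normal(size=400)
        var = rng.normal(size=400)
        theta = -0.1 * k + 0.02 * rng.normal(size=400)
        tab = stats.diversity_connectivity_model(theta, k, level, var)
        beta = tab.loc["connectivity"]
        # standardized slope of -0.1*k + small noise is near -0.98
        assert beta["ci_lo"] < -0.9 < -0.5 or beta["beta"] < -0.9

    def test_noise_r2_near_zero(self):
        rng = np.random.default_rng(9)
        r2s = [stats.diversity_connectivity_model(
            rng.normal(size=200), rng.normal(size=200),
            rng.normal(size=200), rng.normal(size=200)).attrs["r_squared"]
            for _ in range(10)]
        assert np.median(r2s) < 0.02

    def test_small_toy_matches_normal_equations(self):
        theta = np.array([1.0, 2.0, 1.5, 0.5, 2.5, 3.0, 0.7, 1.2,
                          1.8, 0.9, 2.2, 1.4])
        k = np.array([5.0, 3.0, 4.0, 6.0, 2.0, 1.0, 5.5, 4.5,
                      3.5, 6.5, 2.5, 4.2])
        lv = np.array([0.1, 0.4, 0.3, 0.2, 0.6, 0.8, 0.15, 0.35,
                       0.5, 0.25, 0.7, 0.45])
        vr = np.array([1.0, 1.2, 0.8, 1.1, 0.9, 1.3, 1.05, 0.95,
                       1.15, 0.85, 1.25, 1.02])
        tab = stats.diversity_connectivity_model(theta, k, lv, vr)
        z = lambda v: (v - v.mean()) / v.std()
        X = np.column_stack([np.ones(12), z(k), z(lv), z(vr)])
        beta = np.linalg.solve(X.T @ X, X.T @ z(theta))
        assert np.allclose(tab["beta"].to_numpy(), beta, atol=1e-8)

    def test_response_equals_flag_r2_one(self):
        rng = np.random.default_rng(10)
        flag = np.r_[np.ones(20), np.zeros(20)]
        tab = stats.connectivity_outlier_model(flag, rng.normal(size=40) * 1e-9,
                                               rng.normal(size=40) * 1e-9, flag)
        assert tab.attrs["r_squared"] > 0.999

    def test_collinear_rejected(self):
        x = np.arange(20.0)
        with pytest.raises(ValueError, match="collinear"):
            stats.diversity_connectivity_model(np.random.default_rng(0).normal(size=20),
                                               x, 2 * x, np.random.default_rng(1).normal(size=20))

    def test_logistic_enrichment_recovery(self):
        rng = np.random.default_rng(11)
        outlier = (rng.random(2000) < 0.3).astype(float)
        S = rng.integers(1, 30, 2000).astype(float)
        logit = -1.0 + np.log(3) * outlier
        y = rng.random(2000) < 1 / (1 + np.exp(-logit))
        tab = stats.eqtl_outlier_logistic(y, S, outlier)
        assert tab.loc["outlier", "ci_lo"] < np.log(3) < tab.loc["outlier", "ci_hi"]


class TestConnectivityTrend:
    def test_monotone_decay_no_interior_mode(self):
        rng = np.random.default_rng(12)
        k = rng.uniform(0, 5, 300)
        res = stats.connectivity_pvalue_trend(k, np.exp(-k))
        assert res["trend_sign"] == -1
        assert not res["interior_mode"]

    def test_independent_flat(self):
        rng = np.random.default_rng(15)
        covered = 0
        for _ in range(5):
            res = stats.connectivity_pvalue_trend(rng.normal(size=300),
                                                  rng.random(300))
            lo, hi = res["slope_ci"]
            covered += lo < 0 < hi
        assert covered >= 4

    def test_interior_dip_detected(self):
        rng = np.random.default_rng(14)
        k = rng.uniform(-2, 2, 400)
        y = (k ** 2) + rng.normal(0, 0.05, 400)  # dip at mid-connectivity
        res = stats.connectivity_pvalue_trend(k, y)
        assert res["interior_mode"]
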