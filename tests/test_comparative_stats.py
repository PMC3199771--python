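"""Contrasts and sister-pair statistics.

Independent oracles: Brownian-motion theory for contrast variance, closed
forms for the sign test, analytic normal quantiles and statsmodels QuantReg
for the quantile regression, and direct least-squares identities for the
through-origin fits.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import sisterrange as sr
from sisterrange import comparative_stats as cs
from sisterrange.synth import simulate_cherries


class TestStandardizedContrast:
    def test_arithmetic(self):
        assert sr.standardized_contrast(10, 6, 2, 2) == pytest.approx(2.0)

    def test_identical_traits_give_zero(self):
        assert sr.standardized_contrast(5.5, 5.5, 0.3, 1.7) == 0.0

    def test_zero_branch_length_sum_rejected(self):
        with pytest.raises(ValueError):
            sr.standardized_contrast(1, 2, 0, 0)

    @given(st.floats(-50, 50), st.floats(-50, 50),
           st.floats(0.01, 10), st.floats(0.01, 10))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, x1, x2, b1, b2):
        assert sr.standardized_contrast(x1, x2, b1, b2) == pytest.approx(
            -sr.standardized_contrast(x2, x1, b1, b2), abs=1e-12)

    def test_bm_contrast_variance_matches_rate(self, rng):
        """Under BM with rate sigma^2 the contrasts have variance sigma^2."""
        sigma2 = 2.5
        pairs = simulate_cherries(2000, sigma2, rng)
        c = (pairs.x1 - pairs.x2) / np.sqrt(pairs.bl1 + pairs.bl2)
        assert c.var(ddof=1) == pytest.approx(sigma2, rel=0.1)
        assert (c**2).mean() == pytest.approx(sigma2, rel=0.1)


class TestAgeRangeCorrelation:
    def test_perfect_linearity(self):
        r, p = sr.age_range_correlation([1, 2, 3], [10, 20, 30])
        assert r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            sr.age_range_correlation([1, 2, 3], [5, 5, 5])

    def test_null_simulation_r_centered_on_zero(self, rng):
        rs = []
        for _ in range(300):
            ages = rng.exponential(5, size=30)
            overlaps = rng.uniform(0, 100, size=30)
            rs.append(sr.age_range_correlation(ages, overlaps)[0])
        assert abs(np.median(rs)) < 0.1

    def test_spearman_option(self):
        r, _ = sr.age_range_correlation([1, 2, 3, 4], [1, 8, 27, 64],
                                        method="spearman")
        assert r == pytest.approx(1.0)


class TestSignTest:
    def test_all_above_reference_exact_binomial(self):
        z, p = sr.sign_test_overlap(np.arange(1, 11) + 50.0, np.array([10.0]))
        assert p == pytest.approx(2 * 0.5**10, rel=1e-9)

    def test_balanced_split_gives_p_one(self):
        sister = np.array([1, 2, 3, 4, 5, 15, 16, 17, 18, 19], float)
        z, p = sr.sign_test_overlap(sister, np.array([10.0]))
        assert p == pytest.approx(1.0)

    def test_normal_z_matches_hand_formula(self):
        sister = np.concatenate([np.full(70, 20.0), np.full(30, 5.0)])
        z, p = sr.sign_test_overlap(sister, np.array([10.0]))
        assert z == pytest.approx((abs(70 - 50) - 0.5) / 5.0)
        assert z == pytest.approx(3.9)

    def test_normal_approx_close_to_exact_binomial(self):
        for n in (25, 50, 100):
            for frac in (0.3, 0.5, 0.7):
                k = int(round(frac * n))
                sister = np.concatenate([np.full(k, 20.0),
                                         np.full(n - k, 5.0)])
                z, p_norm = sr.sign_test_overlap(sister, np.array([10.0]),
                                                 normal_approx_min_n=1)
                p_exact = stats.binomtest(k, n, 0.5).pvalue
                assert abs(p_norm - p_exact) < 0.01

    def test_all_ties_rejected(self):
        with pytest.raises(ValueError):
            sr.sign_test_overlap(np.full(5, 10.0), np.array([10.0]))


class TestRegressionThroughOrigin:
    def test_exact_line_through_origin(self):
        x = np.arange(1.0, 11.0)
        res = sr.regression_through_origin(2 * x, pd.DataFrame({"x": x}))
        assert res.params["x"] == pytest.approx(2.0)
        assert res.r2 == pytest.approx(1.0)
        assert res.ss_residual == pytest.approx(0.0, abs=1e-18)

    def test_orthogonal_response_gives_zero_slope(self):
        x = np.array([1.0, -1.0, 2.0, -2.0])
        y = np.array([1.0, 1.0, -0.5, -0.5])  # sum(xy) = 0
        res = sr.regression_through_origin(y, pd.DataFrame({"x": x}))
        assert res.params["x"] == pytest.approx(0.0, abs=1e-12)

    def test_ss_decomposition_is_uncentered(self, rng):
        x = rng.normal(size=40)
        y = 0.7 * x + rng.normal(size=40)
        res = sr.regression_through_origin(y, pd.DataFrame({"x": x}))
        assert res.ss_model + res.ss_residual == pytest.approx(float(y @ y))
        assert 0.0 <= res.r2 <= 1.0

    def test_rank_deficient_design_rejected(self):
        x = np.arange(1.0, 11.0)
        with pytest.raises(ValueError):
            sr.regression_through_origin(x, pd.DataFrame({"a": x, "b": 2 * x}))

    def test_estimator_coverage_at_typical_pair_sample_size(self, rng):
        """beta-hat within 2 SE of truth in >=93% of replicates at n=53."""
        hits = 0
        for _ in range(1000):
            x = rng.normal(size=53)
            y = 0.5 * x + rng.normal(size=53)
            res = sr.regression_through_origin(y, pd.DataFrame({"x": x}))
            if abs(res.params["x"] - 0.5) <= 2 * res.bse["x"]:
                hits += 1
        assert hits >= 930

    def test_adding_irrelevant_predictor_never_decreases_r2(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        r2_1 = sr.regression_through_origin(y, pd.DataFrame({"x": x})).r2
        r2_2 = sr.regression_through_origin(
            y, pd.DataFrame({"x": x, "junk": rng.normal(size=30)})).r2
        assert r2_2 >= r2_1 - 1e-12


class TestFactorialRegression:
    def test_pure_main_effect_leaves_interactions_near_zero(self):
        rng = np.random.default_rng(3)
        age = rng.uniform(1, 10, 60)
        dist = rng.uniform(1, 10, 60)
        clim = rng.uniform(1, 10, 60)
        y = 3.0 * age
        res = sr.factorial_regression(y, age, dist, clim)
        assert res.params["age"] == pytest.approx(3.0, abs=1e-8)
        for term in ["age:dist", "age:clim", "dist:clim", "age:dist:clim"]:
            assert abs(res.params[term]) < 1e-8

    def test_joint_row_permutation_invariance(self, rng):
        age = rng.uniform(1, 10, 40)
        dist = rng.uniform(1, 10, 40)
        clim = rng.uniform(1, 10, 40)
        y = age + 0.5 * dist * clim + rng.normal(size=40)
        res1 = sr.factorial_regression(y, age, dist, clim)
        perm = rng.permutation(40)
        res2 = sr.factorial_regression(y[perm], age[perm], dist[perm], clim[perm])
        assert res1.F == pytest.approx(res2.F)
        assert np.allclose(res1.params, res2.params)

    def test_coefficient_recovery_within_2se(self, rng):
        """Known coefficient vector recovered within 2 SE for >=90% of terms."""
        true = {"age": 1.0, "dist": -0.5, "clim": 0.3, "age:dist": 0.2,
                "age:clim": 0.0, "dist:clim": 0.1, "age:dist:clim": 0.05}
        hits = total = 0
        for _ in range(200):
            age = rng.uniform(0, 3, 200)
            dist = rng.uniform(0, 3, 200)
            clim = rng.uniform(0, 3, 200)
            X = cs.factorial_design(age, dist, clim)
            y = X @ pd.Series(true) + rng.normal(size=200)
            res = sr.factorial_regression(y, age, dist, clim)
            for term, b in true.items():
                total += 1
                if abs(res.params[term] - b) <= 2 * res.bse[term]:
                    hits += 1
        assert hits / total >= 0.90


class TestQuantileRegression:
    def test_exact_line_any_tau(self):
        x = np.linspace(0, 10, 30)
        for tau in (0.1, 0.5, 0.9):
            slope, icpt = sr.quantile_regression(x, x, tau=tau)
            assert slope == pytest.approx(1.0, abs=1e-8)
            assert icpt == pytest.approx(0.0, abs=1e-7)

    def test_pure_noise_intercept_is_normal_quantile(self, rng):
        n = 8000  # keeps the quantile's sampling SE well inside the 0.1 band
        x = rng.uniform(0, 1, n)
        y = rng.normal(size=n)
        slope, icpt = sr.quantile_regression(y, x, tau=0.9)
        assert abs(slope) < 0.2
        assert icpt == pytest.approx(stats.norm.ppf(0.9), abs=0.1)

    def test_below_line_fraction_near_tau(self, rng):
        x = rng.uniform(0, 10, 2000)
        y = x + rng.normal(size=2000)
        slope, icpt = sr.quantile_regression(y, x, tau=0.9)
        frac = np.mean(y < icpt + slope * x)
        assert 0.88 <= frac <= 0.92

    def test_matches_statsmodels_quantreg(self, rng):
        """Cross-check the LP solution against the IRLS solver in statsmodels."""
        import statsmodels.api as sm

        x = rng.uniform(0, 10, 300)
        y = 2 * x + rng.standard_t(4, size=300)
        slope, icpt = sr.quantile_regression(y, x, tau=0.9)
        smres = sm.QuantReg(y, sm.add_constant(x)).fit(q=0.9)
        assert slope == pytest.approx(smres.params[1], abs=0.02)
        assert icpt == pytest.approx(smres.params[0], abs=0.1)

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError):
            sr.quantile_regression(np.arange(20.0), np.full(20, 3.0))

    def test_triangular_envelope_slope_recovery(self, rng):
        """Triangular data |dy| <= c*age filled uniformly: tau=0.9 recovers c."""
        c = 2.0
        age = rng.uniform(0.5, 10, 1000)
        y = c * age * rng.uniform(0, 1, 1000)
        slope, _ = sr.quantile_regression(y, age, tau=0.9)
        assert slope == pytest.approx(0.9 * c, rel=0.15)


class TestKSNormality:
    def test_normal_quantiles_give_small_D(self):
        v = stats.norm.ppf((np.arange(1, 101) - 0.5) / 100)
        d, p = sr.ks_normality(v)
        assert d < 0.02
        assert p > 0.9

    def test_two_point_distribution_strongly_rejected(self):
        v = np.concatenate([np.zeros(25), np.ones(25)])
        d, p = sr.ks_normality(v)
        assert d > 0.25
        assert p < 0.01

    def test_uniform_sample_D_matches_simulation_magnitude(self, rng):
        v = rng.uniform(0, 1, 1000)
        d, _ = sr.ks_normality(v)
        assert d == pytest.approx(0.055, abs=0.015)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            sr.ks_normality(np.full(10, 2.0))


class TestContrastTable:
    def test_toy_contrast_matches_hand_computation(self, toy):
        pairs = sr.find_sister_pairs(toy.tree_subst)
        sr.pair_ages(pairs, toy.tree_time)
        rsets = {"RSA": sr.build_range_set(toy.localities, "RSA")}
        tbl = sr.build_contrast_table(pairs, toy.traits, rsets)
        row = tbl[tbl.species_a == "sp1"].iloc[0]
        # SVL 12 vs 14, branch lengths 0.5 + 0.5
        assert row.c_svl == pytest.approx((12 - 14) / math.sqrt(1.0))
        assert row.abs_c_svl == pytest.approx(2.0)
        assert row.age_ma == pytest.approx(1.0)
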