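import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from demgaze.stats import (
    InconsistentCorrelationsError,
    PowerQuery,
    UndefinedCorrelationError,
    bh_fdr,
    compare_dependent_correlations,
    correlation_power_exact,
    paired_t,
    partial_corr,
    pearson,
    required_n_correlation,
    required_n_paired_t,
)


class TestPearson:
    def test_perfect_lines(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson(x, -x).r == pytest.approx(-1.0)

    def test_recovers_population_rho(self):
        rng = np.random.default_rng(0)
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=10_000)
        res = pearson(z[:, 0], z[:, 1])
        assert res.r == pytest.approx(0.5, abs=0.03)
        assert res.df == 10_000 - 2

    def test_zero_variance(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson(np.ones(10), np.arange(10.0))


class TestPartialCorr:
    def test_matches_residual_regression_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = rng.integers(10, 60)
            x, y, c = rng.standard_normal((3, n))
            res = partial_corr(x, y, c)
            # brute-force oracle: correlate OLS residuals
            px = np.polyfit(c, x, 1)
            py = np.polyfit(c, y, 1)
            rx = x - np.polyval(px, c)
            ry = y - np.polyval(py, c)
            r_oracle = np.corrcoef(rx, ry)[0, 1]
            assert res.r == pytest.approx(r_oracle, abs=1e-10)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(2)
        x, y, c = rng.standard_normal((3, 40))
        rxy = np.corrcoef(x, y)[0, 1]
        rxc = np.corrcoef(x, c)[0, 1]
        ryc = np.corrcoef(y, c)[0, 1]
        expected = (rxy - rxc * ryc) / np.sqrt((1 - rxc**2) * (1 - ryc**2))
        assert partial_corr(x, y, c).r == pytest.approx(expected, abs=1e-12)

    def test_exact_functions_of_covariate_degenerate(self):
        c = np.arange(10.0)
        with pytest.raises(UndefinedCorrelationError):
            partial_corr(2 * c + 1, -c, c)

    def test_shared_confounder_removed(self):
        rng = np.random.default_rng(3)
        c = rng.standard_normal(2000)
        x = c + rng.standard_normal(2000)
        y = c + rng.standard_normal(2000)
        assert abs(partial_corr(x, y, c).r) < 0.06

    def test_direct_coupling_survives_adjustment(self):
        rng = np.random.default_rng(4)
        c = rng.standard_normal(2000)
        x = c + rng.standard_normal(2000)
        y = x + rng.standard_normal(2000)
        res = partial_corr(x, y, c)
        assert res.r > 0.3 and res.p < 0.001


class TestPairedT:
    def test_identical_samples(self):
        a = np.arange(5.0)
        t, df, p = paired_t(a, a)
        assert (t, df, p) == (0.0, 4, 1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        a = rng.normal(1.0, 1.0, 12)
        b = rng.normal(0.0, 1.0, 12)
        t, df, p = paired_t(a, b)
        d = a - b
        t_direct = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert t == pytest.approx(t_direct, abs=1e-12)
        assert df == 11
        assert p == pytest.approx(2 * sps.t.sf(abs(t_direct), 11), abs=1e-12)

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(6)
        a, b = rng.standard_normal((2, 15))
        t1, _, p1 = paired_t(a, b)
        t2, _, p2 = paired_t(b, a)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)


class TestDependentCorrelations:
    def test_equal_correlations_null(self):
        t, p = compare_dependent_correlations(0.4, 0.4, 0.3, 50)
        assert t == 0.0 and p == 1.0

    def test_swap_symmetry(self):
        t1, p1 = compare_dependent_correlations(0.6, 0.3, 0.4, 40)
        t2, p2 = compare_dependent_correlations(0.3, 0.6, 0.4, 40)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_inconsistent_matrix_rejected(self):
        with pytest.raises(InconsistentCorrelationsError):
            compare_dependent_correlations(0.9, -0.9, 0.9, 30)

    def test_type_one_error_calibrated(self):
        # trivariate normal null with equal overlapping correlations
        rng = np.random.default_rng(7)
        n, reps = 40, 2000
        R = np.array([[1, 0.4, 0.4], [0.4, 1, 0.5], [0.4, 0.5, 1]])
        L = np.linalg.cholesky(R)
        rej = 0
        for _ in range(reps):
            X = rng.standard_normal((n, 3)) @ L.T
            C = np.corrcoef(X.T)
            t, p = compare_dependent_correlations(C[0, 1], C[0, 2], C[1, 2], n)
            rej += p < 0.05
        assert 0.035 <= rej / reps <= 0.065


class TestFdr:
    def test_single_p_unchanged(self):
        adj, rej = bh_fdr([0.03])
        assert adj[0] == pytest.approx(0.03)

    def test_all_equal(self):
        adj, _ = bh_fdr([0.02, 0.02, 0.02])
        assert np.allclose(adj, 0.02)

    def test_step_up_walkthrough(self):
        adj, rej = bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert rej.all()

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    @settings(max_examples=50, derandomize=True)
    def test_rejections_superset_of_bonferroni(self, ps):
        ps = np.asarray(ps)
        _, rej = bh_fdr(ps, q=0.05)
        bonf = ps <= 0.05 / len(ps)
        assert np.all(rej[bonf])

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestSampleSizes:
    def test_paired_t_required_n(self):
        # one-sided paired t, dz = 0.5, alpha = .05, power .80
        assert required_n_paired_t(PowerQuery(0.5)) == 27

    def test_paired_t_monotone_in_effect_and_alpha(self):
        n_half = required_n_paired_t(PowerQuery(0.25))
        n_full = required_n_paired_t(PowerQuery(0.5))
        assert n_half > n_full
        # quartering law from the noncentrality dz*sqrt(n)
        assert n_half == pytest.approx(4 * n_full, rel=0.15)
        assert required_n_paired_t(PowerQuery(0.5, alpha=0.01)) > n_full

    def test_correlation_exact_power_matches_monte_carlo(self):
        # independent simulation oracle for the exact r-distribution integral
        rng = np.random.default_rng(8)
        n, rho, reps = 23, 0.5, 20_000
        t_crit = sps.t.ppf(0.95, n - 2)
        r_crit = t_crit / np.sqrt(t_crit**2 + n - 2)
        L = np.linalg.cholesky([[1, rho], [rho, 1]])
        z = rng.standard_normal((reps, n, 2)) @ L.T
        zc = z - z.mean(axis=1, keepdims=True)
        num = (zc[:, :, 0] * zc[:, :, 1]).sum(axis=1)
        den = np.sqrt((zc[:, :, 0] ** 2).sum(axis=1) * (zc[:, :, 1] ** 2).sum(axis=1))
        mc_power = float(np.mean(num / den > r_crit))
        assert correlation_power_exact(n, rho, 0.05) == pytest.approx(mc_power, abs=0.02)

    def test_correlation_required_n(self):
        q = PowerQuery(0.5)
        n_exact = required_n_correlation(q, mode="exact")
        assert n_exact == 23  # validated against the Monte-Carlo oracle above
        n_fisher = required_n_correlation(q, mode="fisher-z")
        assert abs(n_fisher - n_exact) <= 3

    def test_fisher_and_exact_agree_for_moderate_effect(self):
        q = PowerQuery(0.3)
        assert abs(
            required_n_correlation(q, "exact") - required_n_correlation(q, "fisher-z")
        ) <= 3

    def test_extreme_effect_floors_at_minimum(self):
        assert required_n_correlation(PowerQuery(0.99), "exact") <= 6

    def test_invalid_query(self):
        with pytest.raises(ValueError):
            PowerQuery(0.5, alpha=1.5)
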