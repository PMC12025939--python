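"""Regression, Chow test, Wilcoxon signed-rank, paired t, normality, LOESS."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from tendont2 import (
    PairedSample,
    T2Profile,
    chow_test,
    loess_smooth,
    ols_fit,
    paired_t_test,
    shapiro_wilk_check,
    wilcoxon_signed_rank,
)


class TestOLS:
    @pytest.mark.parametrize(
        "slope, intercept, x_lo, x_hi",
        [
            (-0.268, 39.5, 0.0, 33.3),   # lateral, pre-treatment tendinotic line
            (0.572, 6.15, 33.3, 66.7),   # middle, post-treatment tendinotic line
            (-0.174, 51.4, 66.7, 100.0), # medial, asymptomatic line
        ],
    )
    def test_noiseless_line_round_trip(self, slope, intercept, x_lo, x_hi):
        x = np.linspace(x_lo, x_hi, 100)
        fit = ols_fit(x, intercept + slope * x)
        assert fit.slope == pytest.approx(slope, abs=1e-9)
        assert fit.intercept == pytest.approx(intercept, abs=1e-9)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_constant_y(self):
        x = np.linspace(0, 10, 7)
        fit = ols_fit(x, np.full(7, 5.0))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(5.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
        y = np.array([3.1, 2.9, 5.0, 8.2, 12.5])
        # independent normal-equations evaluation
        n, sx, sy = len(x), x.sum(), y.sum()
        sxx, sxy = (x * x).sum(), (x * y).sum()
        slope = (n * sxy - sx * sy) / (n * sxx - sx**2)
        intercept = (sy - slope * sx) / n
        fit = ols_fit(x, y)
        assert fit.slope == pytest.approx(slope, rel=1e-12)
        assert fit.intercept == pytest.approx(intercept, rel=1e-12)
        resid = y - intercept - slope * x
        assert fit.rss == pytest.approx(float(resid @ resid), rel=1e-12)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        x = np.linspace(0, 33.3, 34)
        y = 35 - 0.2 * x + rng.normal(0, 3, x.size)
        fit = ols_fit(x, y)
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.intercept == pytest.approx(ref.params[0], rel=1e-10)
        assert fit.slope == pytest.approx(ref.params[1], rel=1e-10)
        assert fit.rss == pytest.approx(ref.ssr, rel=1e-10)

    def test_degenerate_x_raises(self):
        with pytest.raises(ValueError):
            ols_fit(np.full(5, 3.0), np.arange(5.0))


class TestChow:
    def _noisy(self, seed, slope=-0.2, intercept=35.0, n=6, sigma=2.0):
        rng = np.random.default_rng(seed)
        x = np.linspace(0, 30, n)
        return x, intercept + slope * x + rng.normal(0, sigma, n)

    def test_identical_datasets_f_zero(self):
        a = self._noisy(1)
        res = chow_test(a, a)
        assert res.f_stat == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)
        assert res.df1 == 2 and res.df2 == 2 * 6 - 4

    def test_parallel_noiseless_lines_degenerate(self):
        x = np.linspace(0, 30, 8)
        res = chow_test((x, 30 + 0.1 * x), (x, 40 + 0.1 * x))
        assert res.degenerate
        assert res.p_value == 0.0

    def test_identical_noiseless_lines_degenerate_p_one(self):
        x = np.linspace(0, 30, 8)
        res = chow_test((x, 30 + 0.1 * x), (x, 30 + 0.1 * x))
        assert res.degenerate
        assert res.p_value == 1.0

    def test_matches_explicit_rss_oracle(self):
        """F assembled from explicitly computed pooled/split RSS."""
        a = self._noisy(11)
        b = self._noisy(12, slope=-0.35)

        def rss(x, y):
            X = np.column_stack([np.ones_like(x), x])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            r = y - X @ beta
            return float(r @ r)

        rss_a, rss_b = rss(*a), rss(*b)
        xp = np.concatenate([a[0], b[0]])
        yp = np.concatenate([a[1], b[1]])
        rss_p = rss(xp, yp)
        k, n = 2, 12
        f_expected = ((rss_p - rss_a - rss_b) / k) / ((rss_a + rss_b) / (n - 2 * k))
        res = chow_test(a, b)
        assert res.f_stat == pytest.approx(f_expected, rel=1e-10)
        assert res.p_value == pytest.approx(sps.f.sf(f_expected, k, n - 2 * k), rel=1e-10)

    def test_too_small_combined_sample_raises(self):
        x = np.array([0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            chow_test((x[:2], x[:2]), (x, x))  # ols_fit itself rejects n < 3


def brute_force_wilcoxon_p(diff: np.ndarray) -> tuple[float, float]:
    """Independent oracle: full 2^n enumeration on the observed mid-ranks."""
    d = diff[diff != 0]
    ranks = sps.rankdata(np.abs(d))
    n = len(ranks)
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    count = 0
    for signs in product([0, 1], repeat=n):
        w_plus = sum(r for r, s in zip(ranks, signs) if s)
        if min(w_plus, ranks.sum() - w_plus) <= w_obs + 1e-9:
            count += 1
    return w_obs, count / 2**n


class TestWilcoxon:
    def test_all_positive_five(self):
        s = PairedSample(np.zeros(5), np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        res = wilcoxon_signed_rank(s)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / 32)
        assert res.mode == "exact"

    def test_antisymmetric_pair(self):
        s = PairedSample(np.array([0.0, 0.0]), np.array([3.0, -3.0]))
        res = wilcoxon_signed_rank(s)
        assert res.p_value == pytest.approx(1.0)

    def test_all_zero_differences(self):
        s = PairedSample(np.ones(4), np.ones(4))
        res = wilcoxon_signed_rank(s)
        assert res.all_zero and res.p_value == 1.0

    def test_matches_scipy_exact_on_tie_free_data(self):
        rng = np.random.default_rng(8)
        before = rng.normal(40, 5, 12)
        after = before + rng.normal(1, 2, 12)
        res = wilcoxon_signed_rank(PairedSample(before, after), mode="exact")
        ref = sps.wilcoxon(after, before, mode="exact")
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.integers(min_value=-5, max_value=5),
            min_size=2,
            max_size=10,
        ).filter(lambda d: any(v != 0 for v in d))
    )
    def test_exact_p_matches_enumeration(self, diffs):
        """Implementation's exact path equals brute-force 2^n enumeration,
        ties and zeros included."""
        d = np.array(diffs, dtype=float)
        s = PairedSample(np.zeros_like(d), d)
        res = wilcoxon_signed_rank(s, mode="exact")
        w_ref, p_ref = brute_force_wilcoxon_p(d)
        assert res.statistic == pytest.approx(w_ref)
        assert res.p_value == pytest.approx(p_ref, rel=1e-9)

    def test_normal_approximation_reasonable(self):
        rng = np.random.default_rng(3)
        before = rng.normal(40, 5, 40)
        after = before + rng.normal(0.8, 2, 40)
        exact_like = sps.wilcoxon(after, before, mode="approx", correction=True)
        res = wilcoxon_signed_rank(PairedSample(before, after), mode="normal")
        assert res.mode == "normal"
        assert res.p_value == pytest.approx(exact_like.pvalue, abs=0.02)


class TestPairedT:
    def test_plus_minus_one(self):
        t, df, p = paired_t_test(PairedSample(np.zeros(2), np.array([1.0, -1.0])))
        assert t == pytest.approx(0.0)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            paired_t_test(PairedSample(np.zeros(4), np.full(4, 2.0)))

    def test_hand_arithmetic(self):
        # d = 1..5: mean 3, sd sqrt(2.5), t = 3 / (sqrt(2.5)/sqrt(5))
        d = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        t, df, p = paired_t_test(PairedSample(np.zeros(5), d))
        t_expected = 3.0 / (np.sqrt(2.5) / np.sqrt(5))
        assert t == pytest.approx(t_expected, rel=1e-12)
        assert df == 4
        assert p == pytest.approx(2 * sps.t.sf(t_expected, 4), rel=1e-12)

    def test_equals_one_sample_t_on_differences(self):
        rng = np.random.default_rng(5)
        before = rng.normal(50, 10, 15)
        after = before + rng.normal(2, 4, 15)
        t, df, p = paired_t_test(PairedSample(before, after))
        ref = sps.ttest_1samp(after - before, 0.0)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)


class TestShapiro:
    def test_normal_draws_pass(self):
        rng = np.random.default_rng(10)
        w, p, ok = shapiro_wilk_check(rng.normal(0, 1, 500))
        assert ok

    def test_lognormal_draws_fail(self):
        rng = np.random.default_rng(10)
        w, p, ok = shapiro_wilk_check(np.exp(rng.normal(0, 1, 500)))
        assert not ok

    def test_minimal_n(self):
        w, p, ok = shapiro_wilk_check([-1.0, 0.0, 1.0])
        assert 0 <= w <= 1

    def test_constant_raises(self):
        with pytest.raises(ValueError):
            shapiro_wilk_check([2.0, 2.0, 2.0, 2.0])


def make_profile(y, counts=None):
    n = len(y)
    edges = np.linspace(0, 100, n + 1)
    return T2Profile(
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        bin_means=np.asarray(y, dtype=float),
        bin_counts=np.asarray(counts if counts is not None else np.ones(n), dtype=int),
    )


class TestLoess:
    def test_reproduces_line(self):
        x = np.linspace(0.5, 99.5, 100)
        prof = make_profile(30 + 0.2 * x)
        sm = loess_smooth(prof, span=0.3)
        assert np.nanmax(np.abs(sm - prof.bin_means)) < 1e-6

    def test_full_span_on_line(self):
        x = np.linspace(0.5, 99.5, 100)
        prof = make_profile(30 + 0.2 * x)
        sm = loess_smooth(prof, span=1.0)
        assert np.nanmax(np.abs(sm - prof.bin_means)) < 1e-6

    def test_variance_reduction_on_noisy_flat(self):
        rng = np.random.default_rng(4)
        prof = make_profile(40 + rng.normal(0, 3, 100))
        sm = loess_smooth(prof, span=0.4)
        assert np.nanvar(sm) < np.nanvar(prof.bin_means)

    def test_too_few_bins_raises(self):
        prof = make_profile(np.full(8, 40.0))
        with pytest.raises(ValueError):
            loess_smooth(prof, span=0.5)

    def test_tiny_span_raises(self):
        prof = make_profile(np.full(50, 40.0))
        with pytest.raises(ValueError):
            loess_smooth(prof, span=0.01)


class TestRegressionRecovery:
    def test_slope_within_analytic_ci_coverage(self):
        """Fitted segment slopes fall inside their analytic 95% CIs at the
        nominal rate when bin means carry 2 ms Gaussian noise."""
        rng = np.random.default_rng(99)
        x = np.linspace(0.5, 32.8, 33)
        slope_true, intercept_true, sigma = -0.268, 39.5, 2.0
        n, covered = 500, 0
        for _ in range(n):
            y = intercept_true + slope_true * x + rng.normal(0, sigma, x.size)
            fit = ols_fit(x, y)
            se = np.sqrt(fit.rss / (fit.n - 2) / np.sum((x - x.mean()) ** 2))
            tcrit = sps.t.ppf(0.975, fit.n - 2)
            if abs(fit.slope - slope_true) <= tcrit * se:
                covered += 1
        assert covered / n >= 0.93
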