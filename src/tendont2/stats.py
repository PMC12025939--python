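"""Statistical layer for T2 profile comparison.

Per-segment straight-line regression of T2 profiles against normalized
length, the Chow F-test for a structural change between two regressions
(the pre- vs post-treatment comparison), the Wilcoxon signed-rank test on
paired segment means, the paired t-test for clinical scores, a
Shapiro-Wilk normality check, and locally weighted smoothing for profile
plots.

Conventions
-----------
* Regression x is the global normalized-length coordinate in percent; the
  intercept is always the extrapolation to x = 0 (the footprint), even for
  the middle and medial segments.  This keeps slopes and intercepts of
  different segments on one scale.
* All tests are two-sided at alpha = 0.05 unless stated otherwise; no
  multiple-testing correction is applied across segments (results are
  reported per segment).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess

from .profiling import T2Profile

__all__ = [
    "RegressionFit",
    "ChowResult",
    "PairedSample",
    "WilcoxonResult",
    "ols_fit",
    "chow_test",
    "wilcoxon_signed_rank",
    "paired_t_test",
    "shapiro_wilk_check",
    "loess_smooth",
]

ALPHA = 0.05


@dataclass
class RegressionFit:
    """Straight-line least-squares fit of T2 (ms) against position (%)."""

    slope: float  #: ms per percent length
    intercept: float  #: ms at global x = 0
    rss: float  #: residual sum of squares, ms^2
    n: int
    x_range: tuple[float, float]


@dataclass
class ChowResult:
    """Chow structural-change F-test between two regressions.

    ``df1 = 2`` (slope and intercept are both allowed to change) and
    ``df2 = n_a + n_b - 4``.  ``degenerate`` flags the perfect-fit case
    (both residual sums of squares zero), where the F statistic is
    unbounded and p is reported as 0 (separated fits) or 1 (identical
    perfect fits).
    """

    f_stat: float
    df1: int
    df2: int
    p_value: float
    degenerate: bool = False


@dataclass
class PairedSample:
    """Before/after measurements in shared subject order."""

    before: np.ndarray
    after: np.ndarray

    def __post_init__(self) -> None:
        self.before = np.asarray(self.before, dtype=float)
        self.after = np.asarray(self.after, dtype=float)
        if self.before.shape != self.after.shape or self.before.ndim != 1:
            raise ValueError("before/after must be equal-length 1-D samples")
        if self.before.size < 2:
            raise ValueError("need at least 2 pairs")
        if np.any(~np.isfinite(self.before)) or np.any(~np.isfinite(self.after)):
            raise ValueError("missing values are not allowed in paired samples")

    @property
    def differences(self) -> np.ndarray:
        return self.after - self.before


@dataclass
class WilcoxonResult:
    statistic: float  #: W = min(W+, W-)
    p_value: float
    n_used: int  #: pairs remaining after zero-difference removal
    mode: str  #: "exact" or "normal"
    all_zero: bool = False


def ols_fit(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    """Ordinary least squares of y on x (with intercept).

    ``x`` stays in the global percent coordinate — it is not re-zeroed per
    segment — so intercepts of different segments are comparable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 (x, y) points")
    if np.ptp(x) == 0:
        raise ValueError("x values are all equal; slope is undefined")
    X = np.column_stack([np.ones_like(x), x])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return RegressionFit(
        slope=float(coef[1]),
        intercept=float(coef[0]),
        rss=float(resid @ resid),
        n=int(x.size),
        x_range=(float(x.min()), float(x.max())),
    )


def chow_test(
    a: tuple[np.ndarray, np.ndarray], b: tuple[np.ndarray, np.ndarray]
) -> ChowResult:
    """Chow test for a structural change between two straight-line fits.

    With k = 2 parameters (slope and intercept),

        F = [(RSS_pooled - RSS_a - RSS_b) / k]
            / [(RSS_a + RSS_b) / (n_a + n_b - 2k)]

    and p is the upper tail of F(k, n_a + n_b - 2k).  If both separate
    fits are perfect (RSS_a + RSS_b = 0) the statistic is degenerate: p is
    0 when pooling leaves any residual (truly separated lines) and 1 when
    the pooled fit is also perfect (identical lines).
    """
    xa, ya = (np.asarray(v, dtype=float) for v in a)
    xb, yb = (np.asarray(v, dtype=float) for v in b)
    fit_a = ols_fit(xa, ya)
    fit_b = ols_fit(xb, yb)
    pooled = ols_fit(np.concatenate([xa, xb]), np.concatenate([ya, yb]))
    k = 2
    n = fit_a.n + fit_b.n
    df2 = n - 2 * k
    if df2 < 1:
        raise ValueError("need a combined sample of at least 2k + 1 points")
    rss_sep = fit_a.rss + fit_b.rss
    rss_gain = max(pooled.rss - rss_sep, 0.0)
    # tolerance scaled to the data: perfect fits within float roundoff
    tiny = 1e-12 * max(1.0, float(np.sum(ya**2) + np.sum(yb**2)))
    if rss_sep <= tiny:
        if rss_gain <= tiny:
            return ChowResult(0.0, k, df2, 1.0, degenerate=True)
        return ChowResult(float("inf"), k, df2, 0.0, degenerate=True)
    f = (rss_gain / k) / (rss_sep / df2)
    return ChowResult(float(f), k, df2, float(sps.f.sf(f, k, df2)))


def _signed_ranks(diff: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mid-ranks of |d| and signs, after dropping zero differences."""
    d = diff[diff != 0]
    ranks = sps.rankdata(np.abs(d))  # mid-ranks for ties
    return ranks, np.sign(d)


def wilcoxon_signed_rank(
    sample: PairedSample, mode: str = "auto"
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (classic treatment, not Pratt's); tied
    absolute differences receive mid-ranks.  The statistic is
    ``W = min(W+, W-)``.  The p-value is exact — enumeration of all 2^n
    sign assignments on the observed ranks, which remains valid under
    ties — for n <= 25 (``mode="auto"`` or ``"exact"``), otherwise a
    normal approximation with tie correction and continuity correction.

    If every difference is zero the test is vacuous: p = 1 with
    ``all_zero=True``.
    """
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    d = sample.differences
    ranks, signs = _signed_ranks(d)
    n = ranks.size
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, "exact", all_zero=True)
    w_plus = float(ranks[signs > 0].sum())
    w_minus = float(ranks[signs < 0].sum())
    w = min(w_plus, w_minus)

    use_exact = mode == "exact" or (mode == "auto" and n <= 25)
    if use_exact:
        if n > 25:
            raise ValueError("exact enumeration limited to n <= 25")
        # Exact null distribution of W+ over all 2^n equally likely sign
        # patterns, by convolution.  Mid-ranks are half-integers, so work
        # with doubled ranks to stay on an integer lattice.
        r2 = np.rint(2 * ranks).astype(int)
        total2 = int(r2.sum())
        counts = np.zeros(total2 + 1)
        counts[0] = 1.0
        for r in r2:
            counts[r:] += counts[: counts.size - r].copy()
        # two-sided: P(min(W+, W-) <= w); W- = T - W+ with T = sum of ranks
        support2 = np.arange(total2 + 1)
        w_lo2 = np.minimum(support2, total2 - support2)
        p = float(counts[w_lo2 <= 2 * w + 1e-9].sum() / 2.0**n)
        return WilcoxonResult(w, min(p, 1.0), n, "exact")

    mean_w = n * (n + 1) / 4.0
    # variance with tie correction over groups of tied |d|
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / 48.0
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w - mean_w + 0.5) / np.sqrt(var_w)  # continuity-corrected
    p = float(min(1.0, 2.0 * sps.norm.cdf(z)))
    return WilcoxonResult(w, p, n, "normal")


def paired_t_test(sample: PairedSample) -> tuple[float, int, float]:
    """Two-sided paired t-test; returns (t, df, p).

    Equivalent to a one-sample t-test on the differences.  Zero variance of
    the differences leaves t undefined and raises.
    """
    d = sample.differences
    if np.std(d, ddof=1) == 0:
        raise ValueError(
            "paired differences have zero variance; the t statistic is undefined"
        )
    t, p = sps.ttest_rel(sample.after, sample.before)
    return float(t), int(d.size - 1), float(p)


def shapiro_wilk_check(values: Sequence[float]) -> tuple[float, float, bool]:
    """Shapiro-Wilk normality test; returns (W, p, normal_at_0.05).

    The flag is True when the test does not reject normality at
    alpha = 0.05.  Valid for 3 <= n <= 5000; constant input raises.
    """
    v = np.asarray(values, dtype=float)
    if not 3 <= v.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(v) == 0:
        raise ValueError("constant sample; normality test undefined")
    w, p = sps.shapiro(v)
    return float(w), float(p), bool(p >= ALPHA)


def loess_smooth(profile: T2Profile, span: float = 0.3) -> np.ndarray:
    """Locally weighted linear smoothing of a profile, for plotting only.

    Tricube-weighted local linear regression (LOWESS) of the nonempty bin
    means against bin centers, evaluated at every nonempty bin center.
    ``span`` is the fraction of points in each local window.  The smoothed
    curve never feeds the segment regressions or the Chow test.

    Returns an array aligned with ``profile.bin_centers`` (NaN at empty
    bins).
    """
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    sel = profile.nonempty & np.isfinite(profile.bin_means)
    x = profile.bin_centers[sel]
    y = profile.bin_means[sel]
    if x.size < 10:
        raise ValueError("need >= 10 nonempty bins to smooth")
    if span * x.size < 3:
        raise ValueError("span too small: local windows cover < 3 points")
    sm = lowess(y, x, frac=span, it=0, return_sorted=False)
    out = np.full(profile.bin_centers.shape, np.nan)
    out[sel] = sm
    return out
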