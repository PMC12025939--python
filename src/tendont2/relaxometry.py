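"""Per-voxel T2 relaxometry from multi-echo magnitude images.

The decay model is mono-exponential, ``S(TE) = S0 * exp(-TE / T2)``.  The
default estimator is unweighted log-linear least squares (a straight-line
fit of ``ln S`` against TE); a nonlinear signal-domain least-squares
estimator is available for bias studies, optionally with an additive
constant offset to absorb noise floors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .phantom import MultiEchoImage

__all__ = ["T2Map", "FitResult", "fit_t2_loglinear", "fit_t2_nls", "compute_t2_map"]

# zero/negative signals are clipped to this fraction of the voxel's peak
# before the log (magnitude data are non-negative; synthetic edge cases may
# contain exact zeros)
_CLIP_FRACTION = 1e-6
# voxels with more clipped echoes than this are marked invalid
_MAX_CLIPPED = 2
# slopes shallower than this (1/ms) mean T2 > 1e9 ms: no physical decay
_MIN_DECAY_SLOPE = -1e-9


@dataclass
class FitResult:
    """Single-voxel decay fit: T2 (ms), S0, R^2 of the fit, validity."""

    t2: float
    s0: float
    r2: float
    valid: bool
    fallback: bool = False  #: NLS only: log-linear result used instead


@dataclass
class T2Map:
    """Voxelwise T2 fit over a grid.

    Arrays share the image grid shape.  ``t2`` and ``s0`` are NaN, and
    ``r2`` is 0, wherever ``valid`` is False (outside the fit support or
    where the decay fit failed).
    """

    t2: np.ndarray
    s0: np.ndarray
    r2: np.ndarray
    valid: np.ndarray
    echo_train: tuple[float, ...]
    voxel_spacing: tuple[float, float]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.t2.shape


def _r2_of(residuals: np.ndarray, y: np.ndarray) -> float:
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return max(0.0, 1.0 - ss_res / ss_tot)


def fit_t2_loglinear(
    signal: np.ndarray, echo_train: np.ndarray
) -> FitResult:
    """Fit T2 by straight-line least squares of ln(signal) vs TE.

    ``t2 = -1 / slope`` and ``s0 = exp(intercept)``; R^2 is computed in the
    log domain.  Zero or negative signals are clipped to ``1e-6`` of the
    voxel's peak before the log (magnitude data are non-negative, but
    synthetic edge cases may contain zeros); a voxel with more than two
    clipped echoes, or with a non-decaying fit (slope at or above zero up
    to roundoff), is returned invalid rather than raising.
    """
    y = np.asarray(signal, dtype=float)
    te = np.asarray(echo_train, dtype=float)
    if y.size != te.size:
        raise ValueError("signal and echo_train lengths differ")
    if te.size < 3:
        return FitResult(np.nan, np.nan, 0.0, valid=False)
    peak = float(np.max(y))
    if not np.isfinite(peak) or peak <= 0:
        return FitResult(np.nan, np.nan, 0.0, valid=False)
    floor = _CLIP_FRACTION * peak
    n_clipped = int(np.sum(y <= 0))
    if n_clipped > _MAX_CLIPPED or te.size - n_clipped < 3:
        return FitResult(np.nan, np.nan, 0.0, valid=False)
    ly = np.log(np.where(y > 0, y, floor))
    slope, intercept = np.polyfit(te, ly, 1)
    if slope >= _MIN_DECAY_SLOPE:
        return FitResult(np.nan, np.nan, 0.0, valid=False)
    resid = ly - (intercept + slope * te)
    return FitResult(
        t2=-1.0 / slope, s0=float(np.exp(intercept)), r2=_r2_of(resid, ly), valid=True
    )


def fit_t2_nls(
    signal: np.ndarray,
    echo_train: np.ndarray,
    init: Optional[tuple[float, float]] = None,
    with_offset: bool = False,
) -> FitResult:
    """Fit T2 by nonlinear least squares in the signal domain.

    Minimizes ``sum (S(TE) - S0 exp(-TE/T2))^2`` (plus a constant offset
    term when ``with_offset``).  Initialization defaults to the log-linear
    solution; on non-convergence the log-linear result is returned with
    ``fallback=True``.  R^2 is computed in the signal domain.
    """
    y = np.asarray(signal, dtype=float)
    te = np.asarray(echo_train, dtype=float)
    ll = fit_t2_loglinear(y, te)
    if init is None:
        if not ll.valid:
            return ll
        t2_0, s0_0 = ll.t2, ll.s0
    else:
        t2_0, s0_0 = init

    try:
        if with_offset:
            def model(t, s0, t2, c):
                return s0 * np.exp(-t / t2) + c

            popt, _ = curve_fit(
                model, te, y, p0=[s0_0, t2_0, 0.0], maxfev=2000,
                bounds=([0, 1e-3, -np.inf], [np.inf, 1e4, np.inf]),
            )
            s0_hat, t2_hat = popt[0], popt[1]
            resid = y - model(te, *popt)
        else:
            def model(t, s0, t2):
                return s0 * np.exp(-t / t2)

            popt, _ = curve_fit(
                model, te, y, p0=[s0_0, t2_0], maxfev=2000,
                bounds=([0, 1e-3], [np.inf, 1e4]),
            )
            s0_hat, t2_hat = popt
            resid = y - model(te, *popt)
    except RuntimeError:
        return FitResult(ll.t2, ll.s0, ll.r2, ll.valid, fallback=True)
    return FitResult(
        t2=float(t2_hat), s0=float(s0_hat), r2=_r2_of(resid, y), valid=True
    )


def compute_t2_map(
    image: MultiEchoImage,
    mask: Optional[np.ndarray] = None,
    method: str = "loglinear",
) -> T2Map:
    """Fit the decay model at every (masked) voxel of a multi-echo image.

    Fits are voxel-independent — no spatial regularization.  ``method`` is
    ``"loglinear"`` or ``"nls"``.
    """
    shape = image.shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match image grid {shape}"
            )
    if method not in ("loglinear", "nls"):
        raise ValueError(f"unknown fit method {method!r}")

    te = np.asarray(image.echo_train, dtype=float)
    stack = image.as_array()  # (n_echo, *grid)
    t2 = np.full(shape, np.nan)
    s0 = np.full(shape, np.nan)
    r2 = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)

    coords = np.argwhere(mask)
    if method == "loglinear" and coords.size:
        # vectorized log-linear path over all masked voxels at once
        sig = stack[(slice(None), *coords.T)]  # (n_echo, n_vox)
        peak = sig.max(axis=0)
        ok = np.isfinite(peak) & (peak > 0)
        floor = _CLIP_FRACTION * np.where(ok, peak, 1.0)
        n_clipped = (sig <= 0).sum(axis=0)
        ok &= (n_clipped <= _MAX_CLIPPED) & (te.size - n_clipped >= 3)
        ly = np.log(np.where(sig > 0, sig, floor))
        te_c = te - te.mean()
        slope = (te_c @ ly) / (te_c @ te_c)
        intercept = ly.mean(axis=0) - slope * te.mean()
        ok &= slope < _MIN_DECAY_SLOPE
        resid = ly - (intercept + np.outer(te, slope))
        ss_res = (resid**2).sum(axis=0)
        ss_tot = ((ly - ly.mean(axis=0)) ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2_v = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
        r2_v = np.clip(r2_v, 0.0, 1.0)
        rr, cc = coords.T
        sel = ok
        t2[rr[sel], cc[sel]] = -1.0 / slope[sel]
        s0[rr[sel], cc[sel]] = np.exp(intercept[sel])
        r2[rr[sel], cc[sel]] = r2_v[sel]
        valid[rr[sel], cc[sel]] = True
    else:
        for r, c in coords:
            res = fit_t2_nls(stack[:, r, c], te)
            if res.valid:
                t2[r, c] = res.t2
                s0[r, c] = res.s0
                r2[r, c] = res.r2
                valid[r, c] = True

    return T2Map(
        t2=t2, s0=s0, r2=r2, valid=valid,
        echo_train=image.echo_train, voxel_spacing=image.voxel_spacing,
    )
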