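"""Locally weighted scatterplot smoothing (LOWESS).

Classic robust local linear smoothing: at each observed x the response is fit
by weighted least squares over the ceil(span * n) nearest neighbours (ties in
distance included), with tricube weights on the scaled distance; optional
robustness iterations down-weight large residuals with bisquare weights of
r / (6 * median|r|). Smoothed values are evaluated at the observed x values
only. Defaults (span 2/3, three robustness iterations) are the method's
classical ones; the study that motivates this module reports no settings, so
both are parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError


@dataclass(frozen=True)
class LowessFit:
    """Smoothed curve evaluated at the sorted predictor values."""

    x_sorted: np.ndarray
    fitted: np.ndarray
    span: float
    robust_iter: int


def _local_fit(x, y, x0, k, robust_w):
    """Tricube-weighted degree-1 fit at x0 over the k nearest neighbours."""
    d = np.abs(x - x0)
    radius = np.partition(d, k - 1)[k - 1]
    if radius == 0.0:
        in_win = d == 0.0
        w = robust_w[in_win]
        if w.sum() == 0.0:
            return float(np.mean(y[in_win]))
        return float(np.sum(w * y[in_win]) / np.sum(w))
    in_win = d <= radius
    u = d[in_win] / radius
    w = (1.0 - u**3) ** 3 * robust_w[in_win]
    xs, ys = x[in_win], y[in_win]
    sw = w.sum()
    if sw == 0.0:
        return float(np.mean(ys))
    xm = np.sum(w * xs) / sw
    ym = np.sum(w * ys) / sw
    sxx = np.sum(w * (xs - xm) ** 2)
    if sxx <= 1e-12 * max(1.0, xm * xm):
        return float(ym)
    slope = np.sum(w * (xs - xm) * (ys - ym)) / sxx
    return float(ym + slope * (x0 - xm))


def lowess_fit(x, y, span: float = 2.0 / 3.0, robust_iter: int = 3) -> LowessFit:
    """Smooth y against x; returns fitted values at the sorted x.

    Requires at least three points, a non-degenerate x, and a window of at
    least two points (``span * n >= 2``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and aligned")
    if x.size < 3:
        raise DegenerateInputError("lowess needs at least 3 points")
    if np.ptp(x) == 0.0:
        raise DegenerateInputError("all x values are equal")
    if not 0.0 < span <= 1.0:
        raise ValueError(f"span must lie in (0, 1], got {span}")
    if robust_iter < 0:
        raise ValueError("robust_iter must be non-negative")
    n = x.size
    k = min(n, math.ceil(span * n))
    if k < 2:
        raise DegenerateInputError(f"window of {k} point(s); need span * n >= 2")

    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    robust_w = np.ones(n)
    fitted = np.empty(n)
    for iteration in range(robust_iter + 1):
        for i in range(n):
            fitted[i] = _local_fit(xs, ys, xs[i], k, robust_w)
        if iteration == robust_iter:
            break
        resid = ys - fitted
        s = np.median(np.abs(resid))
        if s == 0.0:
            break
        u = np.clip(resid / (6.0 * s), -1.0, 1.0)
        robust_w = (1.0 - u**2) ** 2
    return LowessFit(x_sorted=xs, fitted=fitted, span=span, robust_iter=robust_iter)


def window_slope(fit: LowessFit, lo: float, hi: float) -> float:
    """Least-squares slope of the smoothed curve over lo <= x < hi.

    Summarizes the average steepness of the fitted relationship inside a
    predictor window (e.g. the deficient range 0-10 ng/mL).
    """
    mask = (fit.x_sorted >= lo) & (fit.x_sorted < hi)
    if mask.sum() < 2 or np.ptp(fit.x_sorted[mask]) == 0.0:
        raise DegenerateInputError(f"not enough smoothed points in [{lo}, {hi})")
    xw = fit.x_sorted[mask]
    yw = fit.fitted[mask]
    return float(np.polyfit(xw, yw, 1)[0])
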