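"""Comparator marginal screens: MMLE and the Kolmogorov filter.

MMLE screening fits, for each predictor separately, the one-variable logistic
regression of y on X[:, j] and ranks predictors by the magnitude of the
fitted slope.  The Kolmogorov filter ranks predictors by the two-sample
Kolmogorov-Smirnov statistic between the class-conditional empirical CDFs,

    K_j = sup_x | F1_j(x) - F0_j(x) |,

evaluated exactly at the pooled sample points.  Both consume and produce the
same types as the PB-SIS screen so the three methods are interchangeable in a
simulation study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import BinaryDataset
from .screening import ScreeningResult, rank_scores

__all__ = ["MarginalFit", "marginal_logistic_slopes", "screen_mmle",
           "ks_statistics", "screen_kolmogorov"]

# Newton settings for marginal fits; probabilities clamped to stabilize
# weights, slopes capped (on standardized X) under complete separation.
_MAX_ITER = 25
_LL_TOL = 1e-8
_P_CLIP = 1e-10
_SLOPE_CAP = 30.0


@dataclass(frozen=True)
class MarginalFit:
    """One-predictor logistic fit: intercept, slope and convergence state."""

    slope: float
    intercept: float
    converged: bool
    iterations: int
    separated: bool = False


def _marginal_newton(X: np.ndarray, y: np.ndarray):
    """Newton-Raphson for all p marginal logistic fits simultaneously.

    Each fit has two parameters, so the per-predictor Newton step is solved in
    closed form (2x2 system) and vectorized across columns.
    """
    n, p = X.shape
    b0 = np.full(p, _logit(y.mean()))
    b1 = np.zeros(p)
    yv = y.astype(float)[:, None]
    ll_old = np.full(p, -np.inf)
    converged = np.zeros(p, dtype=bool)
    iters = np.zeros(p, dtype=int)
    for it in range(_MAX_ITER):
        eta = b0[None, :] + X * b1[None, :]
        prob = np.clip(_expit(eta), _P_CLIP, 1.0 - _P_CLIP)
        ll = np.sum(yv * np.log(prob) + (1.0 - yv) * np.log1p(-prob), axis=0)
        newly = ~converged & (np.abs(ll - ll_old) < _LL_TOL)
        converged |= newly
        ll_old = ll
        if converged.all():
            break
        active = ~converged
        w = prob * (1.0 - prob)
        r = yv - prob
        g0 = r.sum(axis=0)
        g1 = np.einsum("ij,ij->j", X, r)
        h00 = w.sum(axis=0)
        h01 = np.einsum("ij,ij->j", X, w)
        h11 = np.einsum("ij,ij,ij->j", X, X, w)
        det = h00 * h11 - h01 * h01
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        step0 = (h11 * g0 - h01 * g1) / det
        step1 = (h00 * g1 - h01 * g0) / det
        b0[active] += step0[active]
        b1[active] += step1[active]
        iters[active] = it + 1
    separated = np.abs(b1) > _SLOPE_CAP
    b1 = np.clip(b1, -_SLOPE_CAP, _SLOPE_CAP)
    return b0, b1, converged, iters, separated


def marginal_logistic_slopes(data: BinaryDataset) -> tuple[np.ndarray, list[MarginalFit]]:
    """Marginal logistic slopes for every predictor, on standardized X.

    Predictors are standardized (mean 0, sd 1) before fitting so slope
    magnitudes are comparable across columns.  Non-convergence keeps the last
    Newton iterate with a flag; complete separation caps |slope| at 30.
    """
    data.require_both_classes()
    X = data.X
    sd = X.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    Xs = (X - X.mean(axis=0)) / sd
    b0, b1, conv, iters, sep = _marginal_newton(Xs, data.y)
    fits = [
        MarginalFit(float(b1[j]), float(b0[j]), bool(conv[j]), int(iters[j]), bool(sep[j]))
        for j in range(data.p)
    ]
    return b1, fits


def screen_mmle(data: BinaryDataset, d: int) -> ScreeningResult:
    """MMLE screen: rank predictors by |marginal logistic slope|."""
    slopes, _ = marginal_logistic_slopes(data)
    return rank_scores(slopes, d, "mmle", data.feature_names)


def ks_statistics(data: BinaryDataset) -> np.ndarray:
    """Exact two-sample KS statistic per predictor column.

    The supremum of |F1 - F0| over step functions is attained at sample
    points; we evaluate the ECDF difference after each distinct pooled value.
    Ties within a column are handled by taking the difference at the last
    occurrence of each tied value.
    """
    data.require_both_classes()
    X, y = data.X, data.y
    n, p = X.shape
    n1 = data.n1
    n0 = data.n0
    order = np.argsort(X, axis=0, kind="stable")
    y_sorted = y[order]  # (n, p) class labels in x-order per column
    x_sorted = np.take_along_axis(X, order, axis=0)
    cdf1 = np.cumsum(y_sorted == 1, axis=0) / n1
    cdf0 = np.cumsum(y_sorted == 0, axis=0) / n0
    diff = np.abs(cdf1 - cdf0)
    # only rows where the next sorted value differs are valid ECDF jump points
    valid = np.ones((n, p), dtype=bool)
    valid[:-1] = x_sorted[1:] != x_sorted[:-1]
    diff = np.where(valid, diff, 0.0)
    return diff.max(axis=0)


def screen_kolmogorov(data: BinaryDataset, d: int) -> ScreeningResult:
    """Kolmogorov filter: rank predictors by the two-sample KS statistic."""
    scores = ks_statistics(data)
    return rank_scores(scores, d, "kolmogorov", data.feature_names)


def _expit(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _logit(p: float) -> float:
    p = min(max(p, _P_CLIP), 1.0 - _P_CLIP)
    return float(np.log(p / (1.0 - p)))
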