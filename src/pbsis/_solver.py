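"""Scalar/loop kernel for penalized logistic coordinate descent.

The functions here are written in loop form so that :mod:`numba` can compile
them; when numba is unavailable the same code runs as plain Python (correct
but slow).  The module is private: :mod:`pbsis.penalized` is the public
surface and documents the algorithm.

Penalty family codes: 0 = lasso, 1 = SCAD, 2 = MCP.
"""

from __future__ import annotations

import math

import numpy as np

P_CLIP = 1e-5
COEF_CAP = 30.0
# Convergence is measured on the weighted scale sqrt(v_j)|delta b_j| (the
# scale of the quadratic objective), so near-saturated fits with tiny IRLS
# weights neither crawl through thousands of sweeps nor flag spurious
# non-convergence.  The inner CD threshold is a tenth of the outer one.

LASSO, SCAD, MCP = 0, 1, 2


def _penalty_value(t, lam, fam, shape):
    t = abs(t)
    if fam == LASSO:
        return lam * t
    if fam == SCAD:
        a = shape
        if t <= lam:
            return lam * t
        if t <= a * lam:
            return (2.0 * a * lam * t - t * t - lam * lam) / (2.0 * (a - 1.0))
        return lam * lam * (a + 1.0) / 2.0
    gamma = shape
    if t <= gamma * lam:
        return lam * t - t * t / (2.0 * gamma)
    return 0.5 * gamma * lam * lam


def _univariate(u, v, lam, fam, shape):
    """Exact minimizer of v b^2/2 - u b + P(|b|) over b.

    For lasso this is soft-thresholding scaled by the curvature v.  For SCAD
    and MCP each penalty region contributes a closed-form stationary point;
    because the 1-d problem may be nonconvex when v is small relative to the
    concavity, the objective is evaluated at every region candidate
    (stationary points, region edges, the unpenalized solution) and the best
    is returned.
    """
    if fam == LASSO:
        az = abs(u) - lam
        if az <= 0.0:
            return 0.0
        return math.copysign(az, u) / v
    s = 1.0 if u >= 0.0 else -1.0
    au = abs(u)
    best = 0.0
    best_val = _penalty_value(0.0, lam, fam, shape)
    if fam == MCP:
        gamma = shape
        edge = gamma * lam
        denom = v - 1.0 / gamma
        n_c = 0
        cands = np.empty(3)
        if denom > 0.0:
            b = (au - lam) / denom
            if 0.0 < b <= edge:
                cands[n_c] = b
                n_c += 1
        cands[n_c] = edge
        n_c += 1
        b3 = au / v
        if b3 > edge:
            cands[n_c] = b3
            n_c += 1
    else:  # SCAD
        a = shape
        n_c = 0
        cands = np.empty(5)
        b1 = (au - lam) / v
        if 0.0 < b1 <= lam:
            cands[n_c] = b1
            n_c += 1
        cands[n_c] = lam
        n_c += 1
        denom = v - 1.0 / (a - 1.0)
        if denom > 0.0:
            b2 = (au - a * lam / (a - 1.0)) / denom
            if lam < b2 <= a * lam:
                cands[n_c] = b2
                n_c += 1
        cands[n_c] = a * lam
        n_c += 1
        b3 = au / v
        if b3 > a * lam:
            cands[n_c] = b3
            n_c += 1
    for k in range(n_c):
        b = cands[k]
        val = 0.5 * v * b * b - au * b + _penalty_value(b, lam, fam, shape)
        if val < best_val - 1e-15:
            best = b
            best_val = val
    return s * best


def _cd_irls(Xs, yf, lam, fam, shape, b0, beta, tol, max_outer, max_sweeps):
    """IRLS middle loop with cyclic coordinate descent inner loop.

    ``tol`` bounds the weighted coefficient change sqrt(v_j)|delta b_j|
    across one IRLS iteration.  Operates in place on ``beta`` (standardized
    scale).  Returns (b0, converged, outer_iterations, separated).
    """
    inner_tol = 0.1 * tol
    n, d = Xs.shape
    z = np.empty(n)
    w = np.empty(n)
    r = np.empty(n)
    v = np.empty(d)
    old = np.empty(d)
    converged = False
    it = 0
    obj_old = _pen_objective(Xs, yf, b0, beta, lam, fam, shape)
    for it in range(1, max_outer + 1):
        # working response and weights at the current parameters
        for i in range(n):
            eta = b0
            for j in range(d):
                eta += Xs[i, j] * beta[j]
            if eta >= 0.0:
                prob = 1.0 / (1.0 + math.exp(-eta))
            else:
                ex = math.exp(eta)
                prob = ex / (1.0 + ex)
            if prob < P_CLIP:
                prob = P_CLIP
            elif prob > 1.0 - P_CLIP:
                prob = 1.0 - P_CLIP
            wi = prob * (1.0 - prob)
            w[i] = wi
            z[i] = eta + (yf[i] - prob) / wi
            r[i] = z[i] - eta
        wsum = 0.0
        for i in range(n):
            wsum += w[i]
        for j in range(d):
            acc = 0.0
            for i in range(n):
                acc += w[i] * Xs[i, j] * Xs[i, j]
            v[j] = acc / n if acc > 0.0 else 1e-12
        old0 = b0
        for j in range(d):
            old[j] = beta[j]

        # coordinate descent: full sweeps alternating with active-set sweeps;
        # the sweep delta is max_j sqrt(v_j) |change_j| (weighted scale)
        w_int = math.sqrt(wsum / n)
        sweeps = 0
        while sweeps < max_sweeps:
            delta = _sweep_all(Xs, w, r, v, beta, lam, fam, shape, n, d)
            shift = _intercept_step(w, r, wsum, n)
            b0 += shift
            if w_int * abs(shift) > delta:
                delta = w_int * abs(shift)
            sweeps += 1
            if delta < inner_tol:
                break
            while sweeps < max_sweeps:
                delta = _sweep_active(Xs, w, r, v, beta, lam, fam, shape, n, d)
                shift = _intercept_step(w, r, wsum, n)
                b0 += shift
                if w_int * abs(shift) > delta:
                    delta = w_int * abs(shift)
                sweeps += 1
                if delta < inner_tol:
                    break

        for j in range(d):
            if beta[j] > COEF_CAP:
                beta[j] = COEF_CAP
            elif beta[j] < -COEF_CAP:
                beta[j] = -COEF_CAP
        # objective-monotone safeguard: the nonconvex 1-d updates can
        # overshoot after requadratization, so backtrack the outer step
        # until the penalized objective does not increase
        obj_new = _pen_objective(Xs, yf, b0, beta, lam, fam, shape)
        halvings = 0
        while obj_new > obj_old + 1e-12 and halvings < 30:
            b0 = old0 + 0.5 * (b0 - old0)
            for j in range(d):
                beta[j] = old[j] + 0.5 * (beta[j] - old[j])
            obj_new = _pen_objective(Xs, yf, b0, beta, lam, fam, shape)
            halvings += 1
        obj_old = obj_new
        change = w_int * abs(b0 - old0)
        for j in range(d):
            cj = math.sqrt(v[j]) * abs(beta[j] - old[j])
            if cj > change:
                change = cj
        if change < tol:
            converged = True
            break
    separated = False
    for j in range(d):
        if abs(beta[j]) >= COEF_CAP:
            separated = True
    return b0, converged, it, separated


def _coord_step(Xs, w, r, v, beta, lam, fam, shape, n, j):
    bj = beta[j]
    acc = 0.0
    for i in range(n):
        acc += w[i] * Xs[i, j] * r[i]
    u = acc / n + v[j] * bj
    new = _univariate(u, v[j], lam, fam, shape)
    if new != bj:
        diff = bj - new
        for i in range(n):
            r[i] += Xs[i, j] * diff
        beta[j] = new
        return math.sqrt(v[j]) * abs(new - bj)
    return 0.0


def _sweep_all(Xs, w, r, v, beta, lam, fam, shape, n, d):
    delta = 0.0
    for j in range(d):
        c = _coord_step(Xs, w, r, v, beta, lam, fam, shape, n, j)
        if c > delta:
            delta = c
    return delta


def _sweep_active(Xs, w, r, v, beta, lam, fam, shape, n, d):
    delta = 0.0
    for j in range(d):
        if beta[j] != 0.0:
            c = _coord_step(Xs, w, r, v, beta, lam, fam, shape, n, j)
            if c > delta:
                delta = c
    return delta


def _intercept_step(w, r, wsum, n):
    acc = 0.0
    for i in range(n):
        acc += w[i] * r[i]
    shift = acc / wsum
    for i in range(n):
        r[i] -= shift
    return shift


def _pen_objective(Xs, yf, b0, beta, lam, fam, shape):
    """Penalized objective (1/n) * neg-loglik + sum_j P(|beta_j|)."""
    n, d = Xs.shape
    nll = 0.0
    for i in range(n):
        eta = b0
        for j in range(d):
            eta += Xs[i, j] * beta[j]
        if eta > 0.0:
            nll += eta + math.log1p(math.exp(-eta)) - yf[i] * eta
        else:
            nll += math.log1p(math.exp(eta)) - yf[i] * eta
    pen = 0.0
    for j in range(d):
        pen += _penalty_value(beta[j], lam, fam, shape)
    return nll / n + pen


def _deviance(Xs, yf, b0, beta):
    """-2 log-likelihood of the logistic model at (b0, beta)."""
    n, d = Xs.shape
    dev = 0.0
    for i in range(n):
        eta = b0
        for j in range(d):
            eta += Xs[i, j] * beta[j]
        if eta > 0.0:
            dev += 2.0 * (eta + math.log1p(math.exp(-eta)) - yf[i] * eta)
        else:
            dev += 2.0 * (math.log1p(math.exp(eta)) - yf[i] * eta)
    return dev


def _path_cd(Xs, yf, lams, fam, shape, tol, max_outer, max_sweeps,
             dev_ratio_stop, fdev):
    """Warm-started coordinate-descent fits down a decreasing lambda grid.

    The path terminates early when the fit approaches saturation, under the
    usual GLM-path rules: the fitted deviance falls below
    (1 - dev_ratio_stop) of the null deviance, the per-step deviance
    improvement falls below fdev times the null deviance, or a coefficient
    hits the separation cap.  Beyond any of these points further lambdas only
    chase a diverging or stationary fit.  Returns the number of lambdas
    actually fitted.
    """
    n, d = Xs.shape
    nlam = lams.shape[0]
    B0 = np.zeros(nlam)
    B = np.zeros((nlam, d))
    dev = np.zeros(nlam)
    iters = np.zeros(nlam, dtype=np.int64)
    conv = np.zeros(nlam, dtype=np.bool_)
    sep = np.zeros(nlam, dtype=np.bool_)
    ybar = 0.0
    for i in range(n):
        ybar += yf[i]
    ybar /= n
    b0 = math.log(ybar / (1.0 - ybar))
    beta = np.zeros(d)
    null_dev = _deviance(Xs, yf, b0, np.zeros(d))
    nfit = 0
    for k in range(nlam):
        b0, c, it, s = _cd_irls(
            Xs, yf, lams[k], fam, shape, b0, beta, tol, max_outer, max_sweeps
        )
        B0[k] = b0
        for j in range(d):
            B[k, j] = beta[j]
        dev[k] = _deviance(Xs, yf, b0, beta)
        iters[k] = it
        conv[k] = c
        sep[k] = s
        nfit = k + 1
        if dev[k] < (1.0 - dev_ratio_stop) * null_dev:
            break
        if fam == LASSO and k > 0 and dev[k - 1] - dev[k] < fdev * (null_dev - dev[k]):
            break
        if s:
            break
    return B0, B, dev, iters, conv, sep, nfit


try:  # compile the kernel when numba is present; plain Python otherwise
    from numba import njit

    _penalty_value = njit(cache=True)(_penalty_value)
    _univariate = njit(cache=True)(_univariate)
    _intercept_step = njit(cache=True)(_intercept_step)
    _coord_step = njit(cache=True)(_coord_step)
    _pen_objective = njit(cache=True)(_pen_objective)
    _sweep_all = njit(cache=True)(_sweep_all)
    _sweep_active = njit(cache=True)(_sweep_active)
    _cd_irls = njit(cache=True)(_cd_irls)
    _deviance = njit(cache=True)(_deviance)
    _path_cd = njit(cache=True)(_path_cd)
    NUMBA = True
except ImportError:  # pragma: no cover
    NUMBA = False
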