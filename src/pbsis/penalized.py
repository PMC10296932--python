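"""Penalized logistic regression: lasso, SCAD and MCP paths with tuning.

The fitting scheme is the standard nested-loop coordinate descent for
penalized GLMs: an outer loop decrements lambda along a log-spaced grid with
warm starts; for each lambda an IRLS (middle) loop forms the weighted
quadratic approximation of the logistic log-likelihood through the working
response

    z_i = eta_i + (y_i - p_i) / w_i,    w_i = p_i (1 - p_i),

and an inner loop runs cyclic coordinate descent on the penalized weighted
least-squares problem.  The one-dimensional lasso update is soft
thresholding; SCAD and MCP coordinates are updated by the exact closed-form
minimizer of the quadratic-plus-penalty problem with the coordinate-wise
second derivative as curvature (the firm-thresholding family), so both
penalties reduce to the lasso continuously as their shape parameter grows.

Tuning is by stratified K-fold cross-validation on validation deviance, or by
AIC / BIC / EBIC computed on the whole-data path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _solver
from .data import BinaryDataset
from .screening import ScreeningResult, screen_pbsis

__all__ = [
    "PenaltySpec",
    "PenalizedFit",
    "RegularizationPath",
    "soft_threshold",
    "irls_working_response",
    "fit_penalized_logistic",
    "lambda_grid",
    "fit_path",
    "select_tuning",
    "two_stage_pbsis",
]

_P_CLIP = 1e-5          # probability clamp inside IRLS
_OUTER_TOL = 1e-5       # weighted coefficient change sqrt(v_j)|d beta_j|
_MAX_OUTER = 100
_MAX_SWEEPS = 1000
_COEF_CAP = 30.0        # |beta| cap (standardized scale) under separation
_DEFAULT_SCAD_A = 3.7
_DEFAULT_MCP_GAMMA = 3.0
_EBIC_GAMMA = 1.0


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty family, level lambda and concavity shape.

    ``shape`` is the SCAD ``a`` (> 2, default 3.7) or the MCP ``gamma``
    (> 1, default 3.0); it is ignored for the lasso.
    """

    family: str
    lam: float
    shape: float | None = None

    def __post_init__(self):
        if self.family not in ("lasso", "scad", "mcp"):
            raise ValueError(f"unknown penalty family {self.family!r}")
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")
        if self.family == "scad":
            shape = _DEFAULT_SCAD_A if self.shape is None else self.shape
            if shape <= 2:
                raise ValueError("SCAD shape a must exceed 2")
            object.__setattr__(self, "shape", shape)
        elif self.family == "mcp":
            shape = _DEFAULT_MCP_GAMMA if self.shape is None else self.shape
            if shape <= 1:
                raise ValueError("MCP shape gamma must exceed 1")
            object.__setattr__(self, "shape", shape)
        else:
            object.__setattr__(self, "shape", None)

    def value(self, t: float) -> float:
        """Penalty value P_lambda(|t|) for a single coefficient."""
        t = abs(t)
        lam = self.lam
        if self.family == "lasso":
            return lam * t
        if self.family == "scad":
            a = self.shape
            if t <= lam:
                return lam * t
            if t <= a * lam:
                return (2 * a * lam * t - t * t - lam * lam) / (2 * (a - 1))
            return lam * lam * (a + 1) / 2
        gamma = self.shape  # mcp
        if t <= gamma * lam:
            return lam * t - t * t / (2 * gamma)
        return 0.5 * gamma * lam * lam


@dataclass
class PenalizedFit:
    """A fitted penalized logistic model on one submodel.

    ``coef`` is on the original predictor scale; ``deviance`` is -2 times the
    unpenalized log-likelihood at the fitted coefficients; ``df`` counts
    nonzero coefficients (intercept excluded).
    """

    intercept: float
    coef: np.ndarray
    penalty: PenaltySpec
    df: int
    deviance: float
    converged: bool
    n_iterations: int
    separated: bool = False

    @property
    def support(self) -> np.ndarray:
        """Indices (within the submodel) of nonzero coefficients."""
        return np.flatnonzero(self.coef)


@dataclass
class RegularizationPath:
    """Ordered sequence of fits along a strictly decreasing lambda grid."""

    lambdas: np.ndarray
    fits: list[PenalizedFit]
    criterion_values: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.lambdas)


def soft_threshold(z: float, gamma: float) -> float:
    """S(z, gamma) = sign(z) * max(|z| - gamma, 0)."""
    if gamma < 0:
        raise ValueError("threshold gamma must be nonnegative")
    az = abs(z) - gamma
    if az <= 0:
        return 0.0
    return math.copysign(az, z)


def irls_working_response(eta: np.ndarray, y: np.ndarray):
    """Working response and weights of the quadratic approximation.

    Probabilities are clamped to [1e-5, 1 - 1e-5] so the weights stay bounded
    away from zero and z stays finite.
    """
    eta = np.asarray(eta, dtype=float)
    y = np.asarray(y, dtype=float)
    prob = np.clip(_expit(eta), _P_CLIP, 1.0 - _P_CLIP)
    w = prob * (1.0 - prob)
    z = eta + (y - prob) / w
    return z, w


def _expit(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _neg_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    """-(1/1) sum log-likelihood of the logistic model (natural log)."""
    # log(1 + e^eta) computed stably
    return float(np.sum(np.logaddexp(0.0, eta) - y * eta))


_FAMILY_CODE = {"lasso": _solver.LASSO, "scad": _solver.SCAD, "mcp": _solver.MCP}


def _univariate_update(u: float, v: float, penalty: PenaltySpec) -> float:
    """Exact minimizer of g(b) = v b^2 / 2 - u b + P(|b|).

    ``v`` is the coordinate-wise second derivative of the weighted quadratic
    loss.  For lasso this is soft thresholding; for SCAD/MCP the minimizer is
    found by comparing the closed-form stationary points of each penalty
    region (the 1-d problem can be nonconvex when v is small relative to the
    concavity, so all region candidates are evaluated).
    """
    shape = 0.0 if penalty.shape is None else penalty.shape
    return float(
        _solver._univariate(u, v, penalty.lam, _FAMILY_CODE[penalty.family], shape)
    )


def _fit_standardized(Xs, y, penalty, b0, beta, tol=_OUTER_TOL):
    """IRLS middle loop around weighted coordinate descent (standardized X)."""
    yf = np.ascontiguousarray(y, dtype=float)
    Xs = np.ascontiguousarray(Xs)
    shape = 0.0 if penalty.shape is None else penalty.shape
    b0, converged, it, separated = _solver._cd_irls(
        Xs, yf, penalty.lam, _FAMILY_CODE[penalty.family], shape,
        float(b0), beta, tol, _MAX_OUTER, _MAX_SWEEPS,
    )
    return b0, beta, converged, it, separated


def _standardize(X):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("cannot standardize constant predictor column(s)")
    return (X - mean) / sd, mean, sd


def fit_penalized_logistic(
    data: BinaryDataset,
    penalty: PenaltySpec,
    warm_start: tuple[float, np.ndarray] | None = None,
) -> PenalizedFit:
    """Fit one penalized logistic regression at a fixed lambda.

    Predictors are standardized internally (the intercept is never
    penalized); returned coefficients are transformed back to the original
    scale.  ``warm_start`` is (intercept, coef) on the *standardized* scale,
    as produced along a path.
    """
    data.require_both_classes()
    Xs, mean, sd = _standardize(data.X)
    n, d = Xs.shape
    if warm_start is None:
        b0 = float(np.log(data.n1 / data.n0))
        beta = np.zeros(d)
    else:
        b0 = float(warm_start[0])
        beta = np.asarray(warm_start[1], dtype=float).copy()
    b0, beta, converged, iters, separated = _fit_standardized(Xs, data.y, penalty, b0, beta)
    coef = beta / sd
    intercept = b0 - float(mean @ coef)
    eta = intercept + data.X @ coef
    deviance = 2.0 * _neg_loglik(eta, data.y.astype(float))
    fit = PenalizedFit(
        intercept=intercept,
        coef=coef,
        penalty=penalty,
        df=int(np.count_nonzero(beta)),
        deviance=deviance,
        converged=converged,
        n_iterations=iters,
        separated=separated,
    )
    fit._std_state = (b0, beta)  # warm-start handle for path fitting
    return fit


def lambda_grid(
    data: BinaryDataset,
    n_lambda: int = 100,
    lambda_min_ratio: float | None = None,
) -> np.ndarray:
    """Log-spaced lambda grid from lambda_max down to its min ratio.

    lambda_max = max_j |(1/n) sum_i x_ij (y_i - ybar)| on standardized X is
    the smallest lambda at which the lasso solution is all-zero.
    """
    if n_lambda < 2:
        raise ValueError("n_lambda must be >= 2")
    Xs, _, _ = _standardize(data.X)
    n = data.n
    resid = data.y.astype(float) - data.y.mean()
    lam_max = float(np.max(np.abs(resid @ Xs)) / n)
    if lam_max <= 0:
        raise ValueError("response carries no marginal signal; lambda_max is 0")
    if lambda_min_ratio is None:
        lambda_min_ratio = 1e-4 if data.n > data.p else 1e-2
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


_DEV_RATIO_STOP = 0.999  # stop once 99.9% of null deviance is explained
_FDEV = 1e-5             # ... or the per-step improvement is below this


def fit_path(
    data: BinaryDataset,
    family: str = "lasso",
    lambdas: np.ndarray | None = None,
    n_lambda: int = 100,
    lambda_min_ratio: float | None = None,
    shape: float | None = None,
) -> RegularizationPath:
    """Fit a regularization path with warm starts down the grid.

    The path terminates early once the fit explains 99.9% of the null
    deviance (the model is then essentially saturated); the returned grid is
    truncated accordingly.
    """
    if lambdas is None:
        lambdas = lambda_grid(data, n_lambda, lambda_min_ratio)
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambdas must be strictly decreasing")
    data.require_both_classes()
    Xs, mean, sd = _standardize(data.X)
    spec_shape = PenaltySpec(family, 0.0, shape).shape
    B0, B, dev, iters, conv, sep, nfit = _solver._path_cd(
        np.ascontiguousarray(Xs),
        np.ascontiguousarray(data.y, dtype=float),
        lambdas,
        _FAMILY_CODE[family],
        0.0 if spec_shape is None else spec_shape,
        _OUTER_TOL,
        _MAX_OUTER,
        _MAX_SWEEPS,
        _DEV_RATIO_STOP,
        _FDEV,
    )
    fits: list[PenalizedFit] = []
    for k in range(nfit):
        coef = B[k] / sd
        intercept = B0[k] - float(mean @ coef)
        fit = PenalizedFit(
            intercept=intercept,
            coef=coef,
            penalty=PenaltySpec(family, float(lambdas[k]), shape),
            df=int(np.count_nonzero(B[k])),
            deviance=float(dev[k]),
            converged=bool(conv[k]),
            n_iterations=int(iters[k]),
            separated=bool(sep[k]),
        )
        fit._std_state = (float(B0[k]), B[k].copy())
        fits.append(fit)
    return RegularizationPath(lambdas=lambdas[:nfit], fits=fits)


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator):
    """Fold labels stratified by class; every fold sees both classes when
    each class has at least k members."""
    n = y.size
    folds = np.empty(n, dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        perm = rng.permutation(idx)
        folds[perm] = np.arange(perm.size) % k
    return folds


def select_tuning(
    path: RegularizationPath,
    criterion: str,
    data: BinaryDataset,
    folds: int = 10,
    seed: int | np.random.SeedSequence | None = None,
) -> PenalizedFit:
    """Select the tuning level along the path; the returned fit is the
    whole-data fit at that lambda (already in the path).

    cv   : stratified K-fold mean validation deviance with the
           one-standard-error rule -- the largest lambda whose mean CV
           deviance is within one standard error of the minimum.
    aic  : deviance + 2 df.
    bic  : deviance + ln(n) df.
    ebic : deviance + ln(n) df + 2 gamma df ln(d), gamma = 1.
    Information-criterion ties break toward the larger lambda (sparser
    model).
    """
    if len(path) == 0:
        raise ValueError("empty path")
    n = data.n
    d = data.p
    dev = np.array([f.deviance for f in path.fits])
    df = np.array([f.df for f in path.fits])
    if criterion == "cv":
        values, se = _cv_deviance(path, data, folds, seed)
        kmin = int(np.argmin(values))
        best = int(np.flatnonzero(values <= values[kmin] + se[kmin])[0])
    elif criterion == "aic":
        values = dev + 2.0 * df
        best = int(np.argmin(values))  # first index = largest lambda on ties
    elif criterion == "bic":
        values = dev + math.log(n) * df
        best = int(np.argmin(values))
    elif criterion == "ebic":
        values = dev + math.log(n) * df + 2.0 * _EBIC_GAMMA * df * math.log(d)
        best = int(np.argmin(values))
    else:
        raise ValueError(f"unknown tuning criterion {criterion!r}")
    path.criterion_values[criterion] = values
    return path.fits[best]


def _cv_deviance(path, data, k, seed):
    """Mean and standard error of validation deviance per lambda."""
    if k < 2:
        raise ValueError("cross-validation needs folds >= 2")
    if min(data.n1, data.n0) < k:
        raise ValueError(
            f"stratified {k}-fold CV requires at least {k} members per class"
        )
    rng = np.random.default_rng(seed)
    fold_of = _stratified_folds(data.y, k, rng)
    family = path.fits[0].penalty.family
    shape = path.fits[0].penalty.shape
    per_fold = np.zeros((k, len(path)))
    for fold in range(k):
        train = fold_of != fold
        test = ~train
        dtrain = BinaryDataset(data.X[train], data.y[train])
        sub = fit_path(dtrain, family, lambdas=path.lambdas, shape=shape)
        Xte = data.X[test]
        yte = data.y[test].astype(float)
        # a fold path may stop early (saturation); its last fit stands in for
        # the remaining lambdas, which it would barely change anyway
        for i in range(len(path)):
            fit = sub.fits[min(i, len(sub.fits) - 1)]
            eta = fit.intercept + Xte @ fit.coef
            per_fold[fold, i] = 2.0 * _neg_loglik(eta, yte)
    return per_fold.mean(axis=0), per_fold.std(axis=0, ddof=1) / math.sqrt(k)


def two_stage_pbsis(
    data: BinaryDataset,
    d: int,
    penalty_family: str = "lasso",
    criterion: str = "cv",
    folds: int = 10,
    seed: int | np.random.SeedSequence | None = None,
    shape: float | None = None,
    n_lambda: int = 100,
    lambda_min_ratio: float | None = None,
) -> tuple[ScreeningResult, PenalizedFit, np.ndarray]:
    """Full two-stage procedure: PB-SIS screen, then penalized fit with
    tuning.  ``final_support`` holds original 0-based predictor indices of the
    stage-2 nonzero coefficients."""
    screen = screen_pbsis(data, d)
    sub = data.subset(screen.selected)
    path = fit_path(sub, penalty_family, n_lambda=n_lambda,
                    lambda_min_ratio=lambda_min_ratio, shape=shape)
    fit = select_tuning(path, criterion, sub, folds=folds, seed=seed)
    final_support = np.sort(screen.selected[fit.support])
    return screen, fit, final_support
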