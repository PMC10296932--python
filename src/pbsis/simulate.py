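"""Synthetic-data generator and Monte-Carlo study drivers.

Designs are rows i.i.d. from N(0, Sigma) with the AR(1) covariance
Sigma_jk = rho^|j-k|, drawn by the exact first-order recursion
X_1 ~ N(0,1), X_j = rho X_{j-1} + sqrt(1-rho^2) eps_j.  The response is
Bernoulli with success probability linked to a sparse linear predictor
eta = beta0 + sum_{j in true set} beta_j x_j through the logit (or probit)
link.  Six standard benchmark models share intercept beta0 = 1 and
coefficient magnitudes 2 and 3 with varying sparsity and signs:

    model 1: x1, x3            beta = ( 2,  3)
    model 2: x1, x6            beta = ( 2, -3)
    model 3: x1, x3, x6        beta = ( 2,  3,  3)
    model 4: x1, x4, x8        beta = ( 2, -3,  3)
    model 5: x1, x3, x6, x10   beta = ( 2,  3,  3,  3)
    model 6: x1, x4, x8, x12   beta = ( 2, -3,  3, -3)

Study drivers evaluate screens (P1, MMMS, RSD) and the full two-stage
procedure (P2, mean final model size) over seeded replicates.  Per-replicate
seeds are derived from the base seed and the replicate index through
``SeedSequence`` spawn keys, so replicates are order-independent and the
studies are reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .competitors import ks_statistics, marginal_logistic_slopes
from .data import BinaryDataset
from .metrics import aggregate, minimum_model_size
from .penalized import two_stage_pbsis
from .screening import marginal_point_biserial, rank_scores

__all__ = [
    "ModelSpec",
    "generate_design",
    "generate_response",
    "generate_dataset",
    "run_screening_study",
    "run_two_stage_study",
]

_TABLE_MODELS = {
    1: ((1, 3), (2.0, 3.0)),
    2: ((1, 6), (2.0, -3.0)),
    3: ((1, 3, 6), (2.0, 3.0, 3.0)),
    4: ((1, 4, 8), (2.0, -3.0, 3.0)),
    5: ((1, 3, 6, 10), (2.0, 3.0, 3.0, 3.0)),
    6: ((1, 4, 8, 12), (2.0, -3.0, 3.0, -3.0)),
}

_SCREENS = {
    "pbsis": marginal_point_biserial,
    "mmle": lambda data: marginal_logistic_slopes(data)[0],
    "kolmogorov": ks_statistics,
}


@dataclass(frozen=True)
class ModelSpec:
    """One simulation scenario: sparse truth, link, and design parameters.

    ``true_indices`` are 1-based (x1 is index 1), matching the usual naming
    of simulated predictors.
    """

    model_id: int
    true_indices: tuple[int, ...]
    beta: tuple[float, ...]
    beta0: float = 1.0
    link: str = "logit"
    n: int = 100
    p: int = 200
    rho: float = 0.0

    def __post_init__(self):
        if len(self.true_indices) != len(self.beta):
            raise ValueError("true_indices and beta must have equal length")
        if min(self.true_indices) < 1 or max(self.true_indices) > self.p:
            raise ValueError("true_indices must lie in 1..p")
        if self.link not in ("logit", "probit"):
            raise ValueError(f"link must be 'logit' or 'probit', got {self.link!r}")
        if not abs(self.rho) < 1:
            raise ValueError("AR(1) parameter rho must satisfy |rho| < 1")

    @classmethod
    def table_model(cls, model_id: int, n: int = 100, p: int = 200,
                    rho: float = 0.0, link: str = "logit") -> "ModelSpec":
        """One of the six benchmark models listed in the module docstring."""
        if model_id not in _TABLE_MODELS:
            raise ValueError(f"model_id must be 1..6, got {model_id}")
        idx, beta = _TABLE_MODELS[model_id]
        return cls(model_id, idx, beta, 1.0, link, n, p, rho)

    @property
    def s(self) -> int:
        return len(self.true_indices)

    @property
    def true_indices0(self) -> np.ndarray:
        """0-based true predictor indices."""
        return np.asarray(self.true_indices, dtype=int) - 1


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_design(n: int, p: int, rho: float, seed=None) -> np.ndarray:
    """n x p design with i.i.d. N(0, Sigma) rows, Sigma_jk = rho^|j-k|.

    Uses the AR(1) recursion across columns, exact for this covariance and
    O(np) in time.
    """
    if not abs(rho) < 1:
        raise ValueError("AR(1) parameter rho must satisfy |rho| < 1")
    if n < 1 or p < 1:
        raise ValueError("need n >= 1 and p >= 1")
    rng = _rng(seed)
    eps = rng.standard_normal((n, p))
    if rho == 0:
        return eps
    X = np.empty((n, p))
    X[:, 0] = eps[:, 0]
    scale = np.sqrt(1.0 - rho * rho)
    for j in range(1, p):
        X[:, j] = rho * X[:, j - 1] + scale * eps[:, j]
    return X


def generate_response(X: np.ndarray, spec: ModelSpec, seed=None) -> np.ndarray:
    """Bernoulli response from the sparse linear predictor of ``spec``."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] < max(spec.true_indices):
        raise ValueError("X has fewer columns than the largest true index")
    eta = spec.beta0 + X[:, spec.true_indices0] @ np.asarray(spec.beta)
    if spec.link == "logit":
        prob = 1.0 / (1.0 + np.exp(-eta))
    else:
        prob = norm.cdf(eta)
    rng = _rng(seed)
    return (rng.uniform(size=X.shape[0]) < prob).astype(np.int8)


def generate_dataset(spec: ModelSpec, seed_key) -> tuple[BinaryDataset, int]:
    """Draw one replicate dataset; redraw (counted) if a class is absent.

    ``seed_key`` is a tuple hashed into a ``SeedSequence`` spawn key, so the
    draw depends only on (base seed, replicate), not on execution order.
    """
    base, *rest = seed_key if isinstance(seed_key, tuple) else (seed_key,)
    redraws = 0
    while True:
        seq = np.random.SeedSequence(entropy=base, spawn_key=(*rest, redraws))
        child_x, child_y = seq.spawn(2)
        X = generate_design(spec.n, spec.p, spec.rho, child_x)
        y = generate_response(X, spec, child_y)
        if 0 < y.sum() < spec.n:
            return BinaryDataset(X, y), redraws
        redraws += 1


def run_screening_study(
    spec: ModelSpec,
    methods=("pbsis", "mmle", "kolmogorov"),
    d_values=(21,),
    n_replicates: int = 1000,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo evaluation of stage-1 screens.

    For each replicate and method the full |score| ranking is computed once;
    containment in the top d follows for every threshold from the replicate's
    minimum model size.  Returns one tidy row per (method, d) with P1, MMMS
    and RSD.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    unknown = set(methods) - set(_SCREENS)
    if unknown:
        raise ValueError(f"unknown screening method(s): {sorted(unknown)}")
    mms = {m: np.empty(n_replicates, dtype=int) for m in methods}
    for r in range(n_replicates):
        data, _ = generate_dataset(spec, (base_seed, r))
        for m in methods:
            scores = _SCREENS[m](data)
            ranking = rank_scores(scores, spec.p, m).ranking
            mms[m][r] = minimum_model_size(ranking + 1, spec.true_indices)
    rows = []
    for m in methods:
        for d in d_values:
            res = aggregate(
                mms[m] <= d,
                min_sizes=mms[m],
                method=m,
                model_id=spec.model_id,
                rho=spec.rho,
                p=spec.p,
                d=int(d),
            )
            rows.append(
                dict(method=m, model_id=spec.model_id, rho=spec.rho, n=spec.n,
                     p=spec.p, d=int(d), P1=res.P, mmms=res.mmms, rsd=res.rsd,
                     n_replicates=res.n_replicates)
            )
    return pd.DataFrame(rows)


def run_two_stage_study(
    spec: ModelSpec,
    penalty_families=("lasso", "scad", "mcp"),
    criteria=("cv", "aic", "bic", "ebic"),
    d: int = 21,
    n_replicates: int = 1000,
    base_seed: int = 0,
    folds: int = 10,
    n_lambda: int = 100,
) -> pd.DataFrame:
    """Monte-Carlo evaluation of the full two-stage procedure.

    Each (penalty, criterion) cell reports P2 (containment of the true set in
    the final support), the mean final model size and the count of replicates
    with a non-converged stage-2 fit.
    """
    if d > spec.p:
        raise ValueError("d must not exceed p")
    cells = [(f, c) for f in penalty_families for c in criteria]
    contained = {cell: np.zeros(n_replicates, dtype=bool) for cell in cells}
    sizes = {cell: np.zeros(n_replicates, dtype=int) for cell in cells}
    nonconv = dict.fromkeys(cells, 0)
    true0 = set(int(j) for j in spec.true_indices0)
    for r in range(n_replicates):
        data, _ = generate_dataset(spec, (base_seed, r))
        cv_seed = np.random.SeedSequence(entropy=base_seed, spawn_key=(r, 9999))
        for fam, crit in cells:
            _, fit, support = two_stage_pbsis(
                data, d, penalty_family=fam, criterion=crit,
                folds=folds, seed=cv_seed, n_lambda=n_lambda,
            )
            contained[(fam, crit)][r] = true0 <= set(int(j) for j in support)
            sizes[(fam, crit)][r] = support.size
            if not fit.converged:
                nonconv[(fam, crit)] += 1
    rows = []
    for fam, crit in cells:
        res = aggregate(contained[(fam, crit)], final_sizes=sizes[(fam, crit)],
                        method="pbsis", penalty=fam, criterion=crit,
                        model_id=spec.model_id, rho=spec.rho, p=spec.p, d=d)
        rows.append(
            dict(penalty=fam, criterion=crit, model_id=spec.model_id,
                 rho=spec.rho, n=spec.n, p=spec.p, d=d, P2=res.P,
                 mean_size=res.mean_size, n_nonconverged=nonconv[(fam, crit)],
                 n_replicates=n_replicates)
        )
    return pd.DataFrame(rows)
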