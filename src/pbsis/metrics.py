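"""Evaluation statistics for screening and selection studies.

P1 / P2 are containment proportions: the fraction of replicates in which the
stage-1 submodel (P1) or the stage-2 final support (P2) contains every true
predictor.  The minimum model size of one replicate is the rank position of
the worst-ranked true predictor, i.e. the smallest d at which screening would
retain them all; its median over replicates is the MMMS and its robust spread
(RSD) is the interquartile range divided by 1.34, the factor that makes the
IQR of a normal sample estimate sigma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StudyResult", "minimum_model_size", "rsd", "aggregate"]

_NORMAL_IQR_FACTOR = 1.34


@dataclass
class StudyResult:
    """Aggregated replicate metrics for one (method, scenario, d) cell."""

    method: str
    P: float
    mmms: float
    rsd: float
    n_replicates: int
    mean_size: float | None = None
    model_id: int | None = None
    rho: float | None = None
    p: int | None = None
    d: int | None = None
    penalty: str | None = None
    criterion: str | None = None


def minimum_model_size(ranking, true_indices) -> int:
    """Worst (1-based) rank held by any true predictor.

    ``ranking`` is a permutation of predictor indices ordered best-first;
    ``true_indices`` uses the same index convention.
    """
    ranking = np.asarray(ranking)
    true_indices = np.asarray(true_indices)
    pos = {int(j): k + 1 for k, j in enumerate(ranking)}
    try:
        return max(pos[int(j)] for j in true_indices)
    except KeyError as err:
        raise ValueError(f"true predictor {err} absent from ranking") from err


def rsd(values) -> float:
    """Robust spread: IQR / 1.34 with type-7 (linear interpolation) quantiles."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("rsd of an empty vector is undefined")
    q1, q3 = np.quantile(values, [0.25, 0.75])
    return float(q3 - q1) / _NORMAL_IQR_FACTOR


def aggregate(
    contained,
    min_sizes=None,
    final_sizes=None,
    method: str = "",
    **identifiers,
) -> StudyResult:
    """Fold per-replicate records into one StudyResult.

    ``contained`` are containment indicators (P is their exact mean);
    ``min_sizes`` the per-replicate minimum model sizes; ``final_sizes`` the
    stage-2 support sizes, when a second stage was run.
    """
    contained = np.asarray(contained, dtype=bool)
    if contained.size == 0:
        raise ValueError("need at least one replicate record")
    P = float(contained.sum()) / contained.size
    if min_sizes is not None:
        min_sizes = np.asarray(min_sizes, dtype=float)
        mmms = float(np.median(min_sizes))
        spread = rsd(min_sizes)
    else:
        mmms = float("nan")
        spread = float("nan")
    mean_size = None if final_sizes is None else float(np.mean(final_sizes))
    return StudyResult(
        method=method,
        P=P,
        mmms=mmms,
        rsd=spread,
        n_replicates=int(contained.size),
        mean_size=mean_size,
        **identifiers,
    )
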