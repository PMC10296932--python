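"""Dataset container shared by every screen and penalized fit.

A :class:`BinaryDataset` couples an ``n x p`` continuous design matrix with a
0/1 response vector.  All screening and fitting routines validate their input
through this class, so degenerate data (a single class, missing values, an
empty design) is rejected in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class DegenerateInputError(ValueError):
    """Raised when data cannot support the requested statistic.

    Examples: a response with only one class, a predictor with zero sample
    variance where nonzero variance is required.
    """


@dataclass
class BinaryDataset:
    """Continuous design matrix plus binary (0/1) response.

    Parameters
    ----------
    X : ndarray, shape (n, p)
        Predictor matrix; finite floats.
    y : ndarray, shape (n,)
        Response coded 0/1.  Both classes must be present for screening or
        fitting.
    feature_names : list of str, optional
        Column labels; defaults to ``x1 .. xp``.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-d array (n samples x p predictors)")
        n, p = self.X.shape
        if n < 2 or p < 1:
            raise ValueError(f"need n >= 2 and p >= 1, got n={n}, p={p}")
        if self.y.shape != (n,):
            raise ValueError(f"y has shape {self.y.shape}, expected ({n},)")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains NaN or infinite values")
        yvals = np.unique(self.y)
        if not np.isin(yvals, [0, 1]).all():
            raise ValueError(f"y must contain only 0 and 1, found values {yvals}")
        self.y = self.y.astype(np.int8)
        if self.feature_names is None:
            self.feature_names = [f"x{j + 1}" for j in range(p)]
        elif len(self.feature_names) != p:
            raise ValueError("feature_names length does not match p")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n1(self) -> int:
        return int(self.y.sum())

    @property
    def n0(self) -> int:
        return self.n - self.n1

    def require_both_classes(self) -> None:
        if self.n1 == 0 or self.n0 == 0:
            raise DegenerateInputError(
                "response y is constant: both classes must be present"
            )

    def subset(self, columns) -> "BinaryDataset":
        """Restrict to the given predictor columns (0-based indices)."""
        cols = np.asarray(columns, dtype=int)
        return BinaryDataset(
            self.X[:, cols],
            self.y,
            [self.feature_names[j] for j in cols],
        )


def read_dataset(
    path,
    response: str,
    positive_class: str | None = None,
    sep: str | None = None,
) -> BinaryDataset:
    """Read a BinaryDataset from a CSV/TSV file.

    The column named ``response`` is the binary outcome; every other numeric
    column is treated as a predictor.  A response holding two string labels is
    mapped to 0/1 via ``positive_class``.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if response not in df.columns:
        raise ValueError(f"response column {response!r} not found in {path}")
    yraw = df[response]
    if positive_class is not None:
        y = (yraw.astype(str) == str(positive_class)).astype(int).to_numpy()
        if y.sum() == 0:
            raise ValueError(
                f"positive class {positive_class!r} absent from column {response!r}"
            )
    else:
        y = yraw.to_numpy()
    Xdf = df.drop(columns=[response]).select_dtypes(include=[np.number])
    return BinaryDataset(Xdf.to_numpy(dtype=float), y, list(Xdf.columns))
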