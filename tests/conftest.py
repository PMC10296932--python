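import numpy as np
import pytest

from pbsis import BinaryDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20230526)


def make_logistic_dataset(rng, n, d, beta=None, beta0=0.3):
    """Random well-conditioned logistic dataset with both classes present."""
    X = rng.standard_normal((n, d))
    if beta is None:
        beta = rng.normal(scale=1.0, size=d)
    eta = beta0 + X @ beta
    y = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    if y.sum() in (0, n):  # pragma: no cover - vanishingly rare at these sizes
        y[0] = 1 - y[0]
    return BinaryDataset(X, y)


@pytest.fixture
def small_dataset(rng):
    return make_logistic_dataset(rng, 60, 5)
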