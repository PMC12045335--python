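import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def simulate_multinomial(rng, n, B, ref_first=True):
    """Draw (X, y) from a baseline-category logit with known coefficients.

    B has shape (K-1, p); X gets an intercept plus standard-normal columns.
    Categories are labelled 1..K with 1 the reference.
    """
    p = B.shape[1]
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
    eta = np.column_stack([np.zeros(n), X @ B.T])
    P = np.exp(eta - eta.max(axis=1, keepdims=True))
    P /= P.sum(axis=1, keepdims=True)
    u = rng.random(n)
    y = 1 + (u[:, None] > P.cumsum(axis=1)).sum(axis=1)
    return X, y


def simulate_ordinal(rng, n, theta, beta):
    """Draw (X, y) from a proportional-odds model, logit P(Y<=k) = theta_k - x'b."""
    p = len(beta)
    X = rng.standard_normal((n, p))
    eta = X @ np.asarray(beta)
    L = eta + rng.logistic(0.0, 1.0, n)
    y = 1 + (L[:, None] > np.asarray(theta)[None, :]).sum(axis=1)
    return X, y
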