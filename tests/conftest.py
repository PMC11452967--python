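"""Shared helpers for the test suite."""

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_linear_dataset(n, p, k, n_causal, noise_sd=0.0, seed=0):
    """Standardized Gaussian design with a sparse linear signal."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    X = (X - X.mean(0)) / X.std(0)
    beta = np.zeros((p, k))
    idx = rng.choice(p, n_causal, replace=False)
    beta[idx] = rng.normal(0, 1.0, size=(n_causal, k))
    Y = X @ beta + noise_sd * rng.normal(size=(n, k))
    Y = (Y - Y.mean(0)) / Y.std(0)
    return X, Y, idx
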