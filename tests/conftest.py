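import numpy as np
import pytest

from fealect import FeatureMatrix, generate_sparse_regression


def orthogonal_design(n: int, d: int, rng: np.random.Generator):
    """Orthonormal, zero-mean columns (d <= n-1) plus a centered response."""
    assert d <= n - 1
    M = rng.standard_normal((n, d))
    M -= M.mean(axis=0)
    Q, _ = np.linalg.qr(M)
    y = rng.standard_normal(n)
    y -= y.mean()
    X = Q[:, :d]
    return FeatureMatrix(X, [f"f{j}" for j in range(d)], y, standardized=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def small_dataset():
    """n=50, d=100 sparse classification problem used across modules."""
    return generate_sparse_regression(n=50, d=100, s=5, snr=5.0, seed=11)
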