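import numpy as np
import pytest

from esplsm import MediationDataset, compute_moments


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dataset(rng, n=40, r=2, p=4, k=2, q=1):
    """Generic well-conditioned dataset with real mediation structure."""
    X = rng.standard_normal((n, k))
    Z = rng.standard_normal((n, q)) if q else np.zeros((n, 0))
    M = X @ rng.standard_normal((k, p)) + (
        Z @ rng.standard_normal((q, p)) if q else 0.0
    ) + rng.standard_normal((n, p))
    Y = M @ rng.standard_normal((p, r)) + X @ rng.standard_normal((k, r)) + (
        Z @ rng.standard_normal((q, r)) if q else 0.0
    ) + rng.standard_normal((n, r))
    return MediationDataset(Y, M, X, Z)


@pytest.fixture
def small_data(rng):
    return random_dataset(rng)


@pytest.fixture
def small_moments(small_data):
    return compute_moments(small_data)
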