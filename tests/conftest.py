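import numpy as np
import pytest

from paretoclust import ClusterParams


@pytest.fixture
def rng():
    return np.random.default_rng(20210424)


@pytest.fixture
def blobs(rng):
    """Two well-separated standard-normal blobs at (+-5, 0), n = 400."""
    X = np.vstack([
        rng.normal([5.0, 0.0], 1.0, size=(200, 2)),
        rng.normal([-5.0, 0.0], 1.0, size=(200, 2)),
    ])
    truth = np.repeat([1, 2], 200)
    return X, truth


def random_theta(rng, K=3, d=2, spread=4.0):
    """A valid random mixture parameter set for oracle comparisons."""
    centers = rng.normal(scale=spread, size=(K, d))
    covs = np.empty((K, d, d))
    for k in range(K):
        A = rng.normal(size=(d, d))
        covs[k] = A @ A.T + 0.5 * np.eye(d)
    props = rng.dirichlet(np.ones(K) * 3.0)
    return ClusterParams(centers, covs, props)
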