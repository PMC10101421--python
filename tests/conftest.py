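import numpy as np
import pytest

from mripem.model import GMMParams, LabeledDataset


def random_gmm(rng: np.random.Generator, K: int, d: int,
               mean_scale: float = 5.0) -> GMMParams:
    """A random valid mixture: Wishart-style PD covariances, Dirichlet weights."""
    weights = rng.dirichlet(np.full(K, 5.0))
    means = rng.normal(scale=mean_scale, size=(K, d))
    covs = np.empty((K, d, d))
    for m in range(K):
        A = rng.normal(size=(d, d + 2))
        covs[m] = A @ A.T / (d + 2) + 0.1 * np.eye(d)
    return GMMParams(weights, means, covs)


def sample_from(params: GMMParams, n: int, rng: np.random.Generator) -> LabeledDataset:
    """Multinomial sampling from a mixture, labels = component of origin."""
    comp = rng.choice(params.K, size=n, p=params.weights)
    X = np.empty((n, params.d))
    for m in range(params.K):
        idx = comp == m
        L = np.linalg.cholesky(params.covariances[m])
        X[idx] = params.means[m] + rng.standard_normal((idx.sum(), params.d)) @ L.T
    return LabeledDataset(X, comp + 1)


@pytest.fixture
def rng():
    return np.random.default_rng(20240613)


@pytest.fixture
def two_blob_data(rng):
    """Well-separated 2-component 1-d mixture (|mu1 - mu2| = 10 sigma)."""
    params = GMMParams(np.array([0.5, 0.5]), np.array([[0.0], [10.0]]),
                       np.stack([np.eye(1), np.eye(1)]))
    return sample_from(params, 500, rng), params
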