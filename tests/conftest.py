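import numpy as np
import pytest

from caesar.likelihood import GPSpec, NodeTimecourses, NoiseState
from caesar.spatial import build_grid_adjacency


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid2x2():
    return build_grid_adjacency(2, 2)


@pytest.fixture
def grid3x3():
    return build_grid_adjacency(3, 3)


@pytest.fixture
def small_data(rng):
    """5 nodes x 8 time points of irregular-variance noise."""
    Y = rng.normal(size=(5, 8)) * rng.uniform(0.5, 2.0, size=(5, 1))
    return NodeTimecourses(Y, np.arange(8) * 2.0)


@pytest.fixture
def default_spec():
    return GPSpec()


@pytest.fixture
def rough_noise(rng):
    """Noise state with non-trivial tau and phi to exercise whitening."""
    return NoiseState(tau=1.7, phi=rng.uniform(0.5, 2.0, size=8))


def dense_cluster_log_marginal(Y_C, K, sigma_diag):
    """Brute-force oracle: log N(vec(Y_C); 0, 11^T (x) K + I (x) Sigma).

    Stacks the n member timecourses node-major and evaluates the full
    nT-dimensional Gaussian density directly.
    """
    from scipy.stats import multivariate_normal

    n, T = Y_C.shape
    cov = np.kron(np.ones((n, n)), K) + np.kron(np.eye(n), np.diag(sigma_diag))
    return multivariate_normal.logpdf(Y_C.ravel(), mean=np.zeros(n * T), cov=cov)
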