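import numpy as np
import pytest

from semastream.em import BatchData, Block
from semastream.model import DataPoint, ModelParameters


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


def random_params(rng, p, r, phi_scale=1.0):
    beta = rng.normal(0.0, 2.0, size=p)
    A = rng.normal(size=(r, r))
    phi = phi_scale * (A @ A.T + 0.5 * np.eye(r))
    return ModelParameters(beta, phi, float(rng.uniform(0.5, 2.0)))


def random_batch(rng, J=5, n_j=6, p=3, r=2, params=None):
    """Small simulated batch drawn from the model itself."""
    params = params or random_params(rng, p, r)
    blocks = []
    for j in range(J):
        nj = int(rng.integers(max(1, n_j - 2), n_j + 3))
        X = np.column_stack([np.ones(nj), rng.standard_normal((nj, p - 1))])
        Z = X[:, :r].copy()
        b = rng.multivariate_normal(np.zeros(r), params.phi)
        y = X @ params.beta + Z @ b + rng.normal(
            0.0, np.sqrt(params.sigma2), size=nj
        )
        blocks.append(Block(j, X, Z, y))
    return BatchData(blocks), params


@pytest.fixture
def small_batch(rng):
    data, params = random_batch(rng)
    return data, params


def batch_to_points(data):
    pts = []
    for b in data.blocks():
        for i in range(len(b.y)):
            pts.append(DataPoint(b.individual_id, b.y[i], b.X[i], b.Z[i]))
    return pts
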