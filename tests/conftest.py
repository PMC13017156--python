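import numpy as np
import pytest

from bnsbm import BlockModelParams, ScoreMatrix, gaussian


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def two_block_theta():
    """Small well-separated 2x2 block model used across modules."""
    return BlockModelParams(
        alpha1=[0.6, 0.4],
        alpha2=[0.5, 0.5],
        Pi=[[0.8, 0.2], [0.1, 0.6]],
        nu0=gaussian(0.0, 1.0, n_free_params=0),
        nu=[[gaussian(2.0, 1.0), gaussian(3.0, 1.5)], [gaussian(-2.0, 1.0), gaussian(1.5, 0.5)]],
    )


@pytest.fixture
def tiny_score_matrix(rng):
    return ScoreMatrix(rng.normal(size=(3, 3)))


def random_theta(rng, B1, B2):
    """A random valid parameter set with separated alternatives."""
    a1 = rng.dirichlet(np.full(B1, 5.0))
    a2 = rng.dirichlet(np.full(B2, 5.0))
    Pi = rng.uniform(0.1, 0.9, size=(B1, B2))
    mu = rng.uniform(1.0, 4.0, size=(B1, B2)) * rng.choice([-1, 1], size=(B1, B2))
    var = rng.uniform(0.5, 2.0, size=(B1, B2))
    return BlockModelParams(
        alpha1=a1,
        alpha2=a2,
        Pi=Pi,
        nu0=gaussian(0.0, 1.0, n_free_params=0),
        nu=[[gaussian(mu[q, l], var[q, l]) for l in range(B2)] for q in range(B1)],
    )
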