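import numpy as np
import pytest

from gfnet import TractographySample, WeightedNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_symmetric(n, rng, density=1.0, scale=1.0):
    """Random nonnegative symmetric weight matrix with zero diagonal."""
    w = rng.random((n, n)) * scale
    if density < 1.0:
        w *= rng.random((n, n)) < density
    w = np.triu(w, 1)
    return w + w.T


def planted_blocks(assignment, intra, inter, rng=None, jitter=0.0):
    """Block-structured symmetric weights from a module assignment."""
    a = np.asarray(assignment)
    same = a[:, None] == a[None, :]
    w = np.where(same, intra, inter).astype(float)
    if jitter and rng is not None:
        noise = rng.normal(0, jitter, size=w.shape)
        w = np.clip(w + np.triu(noise, 1) + np.triu(noise, 1).T, 0, None)
    np.fill_diagonal(w, 0.0)
    return w


@pytest.fixture
def two_cliques():
    """Two disconnected 4-node unit-weight cliques."""
    w = np.zeros((8, 8))
    for block in (slice(0, 4), slice(4, 8)):
        w[block, block] = 1.0
    np.fill_diagonal(w, 0.0)
    return WeightedNetwork(w)


@pytest.fixture
def triangle():
    """Weighted triangle: ab=1, ac=2, bc=3."""
    w = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]])
    return WeightedNetwork(w)


@pytest.fixture
def unit_path3():
    """3-node path a-b-c with unit weights."""
    w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0.0]])
    return WeightedNetwork(w)


@pytest.fixture
def small_sample(rng):
    n = 5
    counts = rng.integers(0, 200, size=(n, n)).astype(float)
    np.fill_diagonal(counts, 0)
    sizes = rng.integers(200, 2000, size=n).astype(float)
    return TractographySample(counts, sizes)
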