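import numpy as np
import pytest

from coexhier import ExpressionMatrix, GeneNetwork, make_two_group_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_network(W, ids=None):
    W = np.asarray(W, dtype=float)
    ids = ids or [f"n{i}" for i in range(W.shape[0])]
    return GeneNetwork(ids, W)


def random_connected_network(rng, n, density=0.6):
    """Random weighted graph kept connected by a spanning path."""
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                W[i, j] = W[j, i] = rng.uniform(0.1, 2.0)
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):
        if W[a, b] == 0:
            W[a, b] = W[b, a] = rng.uniform(0.1, 2.0)
    return make_network(W)


@pytest.fixture(scope="session")
def small_two_group():
    """30 genes, 10+10 samples, strong hierarchy in A, flat B."""
    return make_two_group_dataset(
        n_genes=30, n_a=10, n_b=10, h_a=0.9, h_b=0.0, seed=11
    )


@pytest.fixture
def tiny_expr():
    return ExpressionMatrix(
        ["g1", "g2", "g3"],
        ["s1", "s2", "s3", "s4"],
        np.array([[0.0, 1.0, 2.0, 3.0],
                  [0.5, 2.1, 3.9, 6.2],
                  [5.0, 3.1, 1.2, -0.7]]),
    )
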