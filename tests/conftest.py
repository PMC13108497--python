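import numpy as np
import pytest

from mplexcog.connectome_io import Parcellation


def bfs_reachable(adjacency, start=0):
    """Hand-rolled BFS oracle, independent of the package internals."""
    adjacency = np.asarray(adjacency)
    n = adjacency.shape[0]
    seen = {start}
    frontier = [start]
    while frontier:
        u = frontier.pop()
        for v in range(n):
            if adjacency[u, v] and v not in seen:
                seen.add(v)
                frontier.append(v)
    return seen


def random_connected_graph(rng, n, p=0.3):
    """Erdos-Renyi adjacency, resampled until connected (BFS check)."""
    while True:
        a = (rng.random((n, n)) < p).astype(float)
        a = np.triu(a, 1)
        a = a + a.T
        if len(bfs_reachable(a)) == n:
            return a


def random_tree(rng, n):
    """Random recursive tree adjacency on n nodes."""
    a = np.zeros((n, n))
    for k in range(1, n):
        j = int(rng.integers(0, k))
        a[k, j] = a[j, k] = 1.0
    return a


def distinct_weight_matrix(rng, n, low=0.1, high=1.0):
    """Dense symmetric matrix with distinct positive off-diagonal weights."""
    n_pairs = n * (n - 1) // 2
    vals = np.sort(rng.uniform(low, high, size=n_pairs * 3))[:: 3][:n_pairs]
    rng.shuffle(vals)
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, 1)
    w[iu, ju] = vals
    return w + w.T


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def parc4():
    return Parcellation(
        name="tiny",
        labels=("r0", "r1", "r2", "r3"),
        networks=("frontoparietal", "frontoparietal", "visual", "subcortical"),
    )
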