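import numpy as np
import pytest

from regcn.graph_core import Network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_adjacency(rng, n, p=0.3):
    """Symmetric 0/1 adjacency with zero diagonal."""
    upper = np.triu(rng.random((n, n)) < p, k=1)
    return (upper | upper.T).astype(float)


def network_from_adjacency(A):
    return Network(node_ids=list(range(A.shape[0])), adjacency=A)


def path_graph(n):
    A = np.zeros((n, n))
    for i in range(n - 1):
        A[i, i + 1] = A[i + 1, i] = 1.0
    return network_from_adjacency(A)


def star_graph(n_leaves):
    """Hub is node 0."""
    n = n_leaves + 1
    A = np.zeros((n, n))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    return network_from_adjacency(A)


def two_cliques_bridged(size=5):
    """Two cliques of `size` nodes joined by a single bridge edge."""
    n = 2 * size
    A = np.zeros((n, n))
    for start in (0, size):
        for i in range(start, start + size):
            for j in range(i + 1, start + size):
                A[i, j] = A[j, i] = 1.0
    A[size - 1, size] = A[size, size - 1] = 1.0
    return network_from_adjacency(A)


def count_simple_paths_dfs(A, source, target, length):
    """Exhaustive enumeration of simple paths of exact `length` edges."""
    n = A.shape[0]

    def walk(node, remaining, visited):
        if remaining == 0:
            return 1 if node == target else 0
        total = 0
        for nxt in range(n):
            if A[node, nxt] and nxt not in visited:
                # target may only appear as the final node
                if nxt == target and remaining > 1:
                    continue
                total += walk(nxt, remaining - 1, visited | {nxt})
        return total

    return walk(source, length, {source})
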