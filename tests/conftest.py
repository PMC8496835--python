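import numpy as np
import pytest

from fixbbgcn.graphs import AttributedGraph, GraphDataset


def random_graph(rng, n=None, F=5, S=3, focus=False, labels=False, p_edge=0.6):
    """A random valid attributed graph with asymmetric edge attributes."""
    if n is None:
        n = int(rng.integers(2, 7))
    A = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                A[i, j] = A[j, i] = 1
    E = rng.normal(size=(n, n, S)) * A[..., None]
    X = rng.normal(size=(n, F))
    g = AttributedGraph(
        X, A, E,
        focus=int(rng.integers(n)) if focus else None,
        labels=rng.integers(0, 2, size=54).astype(np.int8) if labels else None,
    )
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def path_graph_3():
    """A 3-node path graph 0-1-2 with distinct directional edge attributes."""
    A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.int8)
    E = np.zeros((3, 3, 2))
    E[0, 1] = [1.0, 2.0]
    E[1, 0] = [-1.0, 0.5]
    E[1, 2] = [3.0, -1.0]
    E[2, 1] = [0.25, 4.0]
    X = np.arange(6, dtype=float).reshape(3, 2)
    return AttributedGraph(X, A, E)


def random_dataset(rng, n_graphs, F=4, S=3, labels=True, p_edge=0.6):
    graphs = [
        random_graph(rng, F=F, S=S, focus=True, labels=labels, p_edge=p_edge)
        for _ in range(n_graphs)
    ]
    return GraphDataset(graphs, F, S, metadata={"seed": 0})
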