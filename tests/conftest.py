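import numpy as np
import pytest

from dkinet import CohortConfig, ConnectivityMatrix, ThresholdedGraph


@pytest.fixture
def small_cohort_config():
    """Fast cohort for plumbing tests: few regions/subjects, one metric."""
    return CohortConfig(n_patients=8, n_controls=7, n_regions=30,
                        metrics=("MK",), ws_k=4, wm_ws_k=6, seed=11)


@pytest.fixture
def paper_cohort_config():
    """The emulated study conditions: 21 patients, 19 controls, 90 regions."""
    return CohortConfig(seed=5, metrics=("MK",))


def graph_from_edges(n, edges, weights=None):
    adj = np.zeros((n, n))
    for idx, (i, j) in enumerate(edges):
        w = 1.0 if weights is None else weights[idx]
        adj[i, j] = adj[j, i] = w
    mode = "binary" if weights is None else "weighted"
    m = n * (n - 1) / 2
    return ThresholdedGraph(labels=[f"n{i}" for i in range(n)], adjacency=adj,
                            sparsity=len(edges) / m if m else 1.0, mode=mode)


@pytest.fixture
def k4():
    return graph_from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])


@pytest.fixture
def star5():
    return graph_from_edges(5, [(0, 1), (0, 2), (0, 3), (0, 4)])


@pytest.fixture
def path4():
    return graph_from_edges(4, [(0, 1), (1, 2), (2, 3)])


def random_correlation_matrix(n, rng):
    """A random symmetric zero-diagonal matrix posing as correlations."""
    a = rng.uniform(-1, 1, size=(n, n))
    a = np.triu(a, 1)
    a = a + a.T
    return ConnectivityMatrix(labels=[f"R{i}" for i in range(n)], values=a,
                              weight_kind="correlation")
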