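import numpy as np
import pytest

from winner import GeneNetwork, fixtures


@pytest.fixture
def triangle():
    """Undirected triangle, all confidences 1."""
    return GeneNetwork([("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 1.0)])


@pytest.fixture
def weighted_path():
    """A-B (0.5), B-C (1.0)."""
    return GeneNetwork([("A", "B", 0.5), ("B", "C", 1.0)])


@pytest.fixture
def directed_chain():
    """A regulates B regulates C, all confidences 1."""
    return GeneNetwork([("A", "B", 1.0), ("B", "C", 1.0)], directed=True)


@pytest.fixture
def scale_free():
    """100-node weighted scale-free fixture."""
    return fixtures.make_scale_free_weighted(100, 2, rng_seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def iterative_oracle_scores(net, damping=0.85, mode="undirected"):
    """Independent dense fixed-point solve of the score equations.

    Built straight from the edge list, separately from the package's
    propagation-matrix code: S = (I - sigma * P)^-1 (1 - sigma) S0 with
    P[i, j] = c(j, i) / d(j).
    """
    nodes = sorted(net.nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    w = np.zeros(n)  # mode-specific incident confidence (for S0)
    I = np.zeros(n)
    d = np.zeros(n)  # distribution mass
    C = np.zeros((n, n))  # C[i, j] = confidence of the edge i collects from j
    for u, v, c in net.edges():
        iu, iv = idx[u], idx[v]
        if mode == "undirected":
            w[iu] += c
            w[iv] += c
            I[iu] += 1
            I[iv] += 1
            d[iu] += c
            d[iv] += c
            C[iu, iv] = c
            C[iv, iu] = c
        elif mode == "upstream":
            # u regulates v: u's stats count out-edges; u collects from v;
            # v distributes along its in-edges
            w[iu] += c
            I[iu] += 1
            d[iv] += c
            C[iu, iv] = c
        elif mode == "downstream":
            w[iv] += c
            I[iv] += 1
            d[iu] += c
            C[iv, iu] = c
    s0 = np.where(I > 0, w**2 / np.maximum(I, 1), 0.0)
    P = np.where(d > 0, C / np.maximum(d, 1e-300), 0.0)
    s = np.linalg.solve(np.eye(n) - damping * P, (1 - damping) * s0)
    return dict(zip(nodes, s))
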