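"""The WINNER scoring engine.

Each gene starts from an initial score derived from its weighted
connectivity,

    S0(i) = exp(2 ln w(i) - ln I(i)) = w(i)^2 / I(i),

where ``w(i)`` is the summed confidence of the gene's interactions and
``I(i)`` their count (genes with no interactions under the active mode
get S0 = 0).  The score is then refined by a damped random-walk update

    S_t(i) = (1 - sigma) * S0(i) + sigma * sum_j c(j, i) * S_{t-1}(j) / d(j)

until the maximum per-gene change drops below a tolerance.  ``sigma``
is the usual PageRank-style damping parameter (default 0.85) and
``d(j)`` is the total confidence of the edges along which gene j
distributes score in the active mode, so each gene passes on its
current score split proportionally to edge confidence.  For an
undirected network with all confidences 1 the converged score equals
the node degree exactly.

Directed variants re-read the same formulas: in *upstream* mode a gene
collects score from the genes it regulates (regulators of high-scoring
targets rank high); in *downstream* mode from its regulators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats

from .network import GeneNetwork, NodeStats, node_stats

__all__ = [
    "RankingConfig",
    "RankingResult",
    "initial_score",
    "propagate_step",
    "rank",
    "rank_directed",
    "ranks_and_percentiles",
]


@dataclass(frozen=True)
class RankingConfig:
    """Parameters of the iterative scoring.

    damping: fraction of score propagated through the network per
    iteration (vs. retained from S0); tol: convergence threshold on the
    maximum per-gene score change; max_iter: iteration cap; mode: one
    of ``undirected``, ``upstream``, ``downstream``.
    """

    damping: float = 0.85
    tol: float = 0.001
    max_iter: int = 200
    mode: str = "undirected"

    def __post_init__(self) -> None:
        if not 0.0 < self.damping < 1.0:
            raise ValueError("damping must be in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.mode not in ("undirected", "upstream", "downstream"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class RankingResult:
    """Converged scores with derived ranks and percentiles.

    Ranks are 1 = best, descending by score, ties averaged.
    Percentiles rescale rank r to (n - r) / (n - 1) * 100, so the top
    gene sits at 100 and the bottom at 0, which lets rankings of
    networks of different sizes be pooled.
    """

    scores: dict[str, float]
    iterations: int
    converged: bool
    ranks: dict[str, float] = field(default_factory=dict)
    percentiles: dict[str, float] = field(default_factory=dict)


def initial_score(stats: dict[str, NodeStats]) -> dict[str, float]:
    """S0(i) = w(i)^2 / I(i); genes isolated under the mode get 0."""
    s0 = {}
    for gene, st in stats.items():
        if st.w < 0:
            raise ValueError(f"negative w for gene {gene}")
        s0[gene] = 0.0 if st.I == 0 else st.w * st.w / st.I
    return s0


def _distribution_weights(net: GeneNetwork, mode: str) -> dict[str, float]:
    """d(j): total confidence of the edges along which j passes score.

    Undirected: w(j).  Upstream mode: score flows target -> regulator,
    so j distributes along its incoming regulatory edges.  Downstream:
    flows regulator -> target, so j distributes along its outgoing
    edges.
    """
    g = net.graph
    d: dict[str, float] = {}
    for gene in g.nodes:
        if mode == "undirected":
            inc = g.edges(gene, data=True)
        elif mode == "upstream":
            inc = g.in_edges(gene, data=True)
        else:  # downstream
            inc = g.out_edges(gene, data=True)
        d[gene] = sum(dd["confidence"] for _, _, dd in inc)
    return d


def _collection_edges(net: GeneNetwork, mode: str):
    """Yield (i, j, c) meaning: gene i collects c * S(j) / d(j) from j."""
    g = net.graph
    if mode == "undirected":
        for u, v, dd in g.edges(data=True):
            c = dd["confidence"]
            yield u, v, c
            yield v, u, c
    elif mode == "upstream":
        # i regulates j: i collects from its targets
        for i, j, dd in g.edges(data=True):
            yield i, j, dd["confidence"]
    else:  # downstream: i is regulated by j, collects from regulators
        for j, i, dd in g.edges(data=True):
            yield i, j, dd["confidence"]


def _propagation_matrix(net: GeneNetwork, mode: str):
    """Dense matrix P with P[i, j] = c(j, i) / d(j); genes with d=0 give 0."""
    nodes = list(net.graph.nodes)
    index = {g: k for k, g in enumerate(nodes)}
    d = _distribution_weights(net, mode)
    n = len(nodes)
    P = np.zeros((n, n))
    for i, j, c in _collection_edges(net, mode):
        dj = d[j]
        if dj > 0:
            P[index[i], index[j]] = c / dj
    return nodes, P


def propagate_step(
    net: GeneNetwork,
    s_prev: dict[str, float],
    s0: dict[str, float],
    config: RankingConfig,
) -> dict[str, float]:
    """One random-walk update of the score vector."""
    nodes, P = _propagation_matrix(net, config.mode)
    prev = np.array([s_prev[g] for g in nodes])
    base = np.array([s0[g] for g in nodes])
    new = (1.0 - config.damping) * base + config.damping * (P @ prev)
    return dict(zip(nodes, new))


def ranks_and_percentiles(
    scores: dict[str, float],
) -> tuple[dict[str, float], dict[str, float]]:
    """Descending average-tie ranks and their percentile rescaling."""
    genes = list(scores)
    vals = np.array([scores[g] for g in genes])
    r = sp_stats.rankdata(-vals, method="average")
    n = len(genes)
    if n > 1:
        pct = (n - r) / (n - 1) * 100.0
    else:
        pct = np.full(n, 100.0)
    return dict(zip(genes, r)), dict(zip(genes, pct))


def rank(
    net: GeneNetwork,
    global_net: GeneNetwork | None = None,
    config: RankingConfig | None = None,
) -> RankingResult:
    """Run the full scoring iteration on ``net`` and derive ranks.

    Genes present in the global interaction collection but outside
    ``net`` hold score 0 and are not ranked here; they enter only
    through expansion.  Stops when the maximum per-gene change drops
    below ``config.tol`` or after ``config.max_iter`` iterations.
    """
    config = config or RankingConfig()
    if config.mode != "undirected" and not net.directed:
        raise ValueError(f"mode {config.mode!r} requires a directed network")
    if net.n_nodes == 0:
        raise ValueError("cannot rank an empty network")

    stats = node_stats(net, global_net, mode=config.mode)
    s0_map = initial_score(stats)

    nodes, P = _propagation_matrix(net, config.mode)
    s0 = np.array([s0_map[g] for g in nodes])
    s = s0.copy()
    converged = False
    iterations = 0
    for iterations in range(1, config.max_iter + 1):
        s_new = (1.0 - config.damping) * s0 + config.damping * (P @ s)
        delta = float(np.max(np.abs(s_new - s))) if len(s) else 0.0
        s = s_new
        if delta < config.tol:
            converged = True
            break

    scores = dict(zip(nodes, s))
    ranks, percentiles = ranks_and_percentiles(scores)
    return RankingResult(
        scores=scores,
        iterations=iterations,
        converged=converged,
        ranks=ranks,
        percentiles=percentiles,
    )


def rank_directed(
    net: GeneNetwork,
    global_net: GeneNetwork | None = None,
    config: RankingConfig | None = None,
) -> RankingResult:
    """Directed-mode ranking; requires ``config.mode`` upstream/downstream."""
    config = config or RankingConfig(mode="upstream")
    if config.mode == "undirected":
        raise ValueError("rank_directed requires mode 'upstream' or 'downstream'")
    if not net.directed:
        raise ValueError("rank_directed requires a directed network")
    return rank(net, global_net, config)


def solve_scores_direct(
    net: GeneNetwork, config: RankingConfig | None = None
) -> dict[str, float]:
    """Closed-form fixed point (I - sigma P) S = (1 - sigma) S0.

    Direct dense solve of the stationary equation; used as an
    independent cross-check of the iterative scores.
    """
    config = config or RankingConfig()
    stats = node_stats(net, None, mode=config.mode)
    s0_map = initial_score(stats)
    nodes, P = _propagation_matrix(net, config.mode)
    s0 = np.array([s0_map[g] for g in nodes])
    A = np.eye(len(nodes)) - config.damping * P
    s = np.linalg.solve(A, (1.0 - config.damping) * s0)
    return dict(zip(nodes, s))
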