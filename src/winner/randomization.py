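"""Network randomization schemes for building null ensembles.

Five schemes are provided, spanning the spectrum from "destroy all
topology" to "preserve as much topology as possible":

* **total rewire** — every edge's endpoints are redrawn uniformly at
  random; only the edge count survives.
* **preserve degree** — repeated double-edge swaps leave every node's
  degree unchanged while shuffling partners.
* **preserve modularity** — double-edge swaps restricted to edge pairs
  whose community-pair labels match, which preserves node degrees and
  within/between-community edge counts, hence the Newman modularity Q
  of a fixed detected partition exactly.
* **add / remove a fraction** — perturb the edge set by a small
  percentage (default 5%) of random additions or deletions.

All schemes leave the node set unchanged.  Because swap/rewire
procedures act on unweighted topology, edge weights are re-drawn with
replacement from the empirical weight distribution of the original
network.  A chi-square goodness-of-fit helper tests whether per-gene
score samples from an ensemble look normally distributed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats as sp_stats

from .network import GeneNetwork

__all__ = [
    "RandomizationConfig",
    "randomize",
    "randomize_total_rewire",
    "randomize_preserve_degree",
    "randomize_preserve_modularity",
    "perturb_edges",
    "resample_weights",
    "normality_chi2",
]

METHODS = (
    "total_rewire",
    "preserve_degree",
    "preserve_modularity",
    "add_fraction",
    "remove_fraction",
)


@dataclass(frozen=True)
class RandomizationConfig:
    method: str = "preserve_degree"
    fraction: float = 0.05
    replicates: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown randomization method {self.method!r}")
        if self.method in ("add_fraction", "remove_fraction") and not (
            0.0 < self.fraction < 1.0
        ):
            raise ValueError("fraction must be in (0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _require_undirected(net: GeneNetwork) -> None:
    if net.directed:
        raise ValueError("randomization schemes are defined for undirected networks")


def resample_weights(template_weights, k: int, rng: np.random.Generator):
    """Draw ``k`` weights with replacement from an empirical multiset."""
    template = np.asarray(list(template_weights), dtype=float)
    if template.size == 0:
        raise ValueError("empty weight template")
    if k == 0:
        return []
    return list(rng.choice(template, size=k, replace=True))


def _rebuild(net: GeneNetwork, pairs, rng: np.random.Generator) -> GeneNetwork:
    """New network on the same nodes with resampled weights on ``pairs``."""
    weights = resample_weights(net.confidences() or [1.0], len(pairs), rng)
    edges = [(u, v, w) for (u, v), w in zip(pairs, weights)]
    return GeneNetwork(edges, nodes=net.nodes, directed=False)


def randomize_total_rewire(net: GeneNetwork, rng: np.random.Generator) -> GeneNetwork:
    """Redraw both endpoints of every edge uniformly; keeps only |E|."""
    _require_undirected(net)
    nodes = net.nodes
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes to rewire")
    m = net.n_edges
    placed: set[frozenset] = set()
    pairs = []
    max_tries = 100 * max(m, 1)
    tries = 0
    while len(pairs) < m:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                "could not place all rewired edges; the network is too dense "
                "for uniform rewiring — use fewer edges"
            )
        u, v = rng.choice(len(nodes), size=2, replace=False)
        key = frozenset((u, v))
        if key in placed:
            continue
        placed.add(key)
        pairs.append((nodes[u], nodes[v]))
    return _rebuild(net, pairs, rng)


def _double_edge_swaps(
    edges: list[tuple[str, str]],
    rng: np.random.Generator,
    n_attempts: int,
    allowed=None,
) -> list[tuple[str, str]]:
    """Degree-preserving double-edge swaps on an undirected edge list.

    Swap (u, v), (x, y) -> (u, y), (x, v), rejecting self-loops and
    duplicates.  ``allowed(a, b)`` may further restrict which edge
    indices can be swapped together (used for modularity preservation).
    """
    edges = list(edges)
    m = len(edges)
    if m < 2:
        return edges
    edge_set = {frozenset(e) for e in edges}
    for _ in range(n_attempts):
        a, b = rng.integers(0, m, size=2)
        if a == b:
            continue
        if allowed is not None and not allowed(a, b):
            continue
        u, v = edges[a]
        x, y = edges[b]
        # swapping second endpoints preserves all four degrees
        if u == y or x == v:
            continue
        new1, new2 = frozenset((u, y)), frozenset((x, v))
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(frozenset((u, v)))
        edge_set.discard(frozenset((x, y)))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[a] = (u, y)
        edges[b] = (x, v)
    return edges


def randomize_preserve_degree(
    net: GeneNetwork, rng: np.random.Generator, swaps_per_edge: int = 10
) -> GeneNetwork:
    """Shuffle partners by double-edge swaps; every degree is unchanged."""
    _require_undirected(net)
    if net.n_edges < 2:
        return _rebuild(net, [(u, v) for u, v, _ in net.edges()], rng)
    edges = [(u, v) for u, v, _ in net.edges()]
    out = _double_edge_swaps(edges, rng, swaps_per_edge * len(edges))
    new = _rebuild(net, out, rng)
    # invariant check: the degree sequence must be untouched
    old_deg = {g: net.degree(g) for g in net.nodes}
    new_deg = {g: new.degree(g) for g in new.nodes}
    assert old_deg == new_deg, "double-edge swap violated the degree sequence"
    return new


def detect_communities(net: GeneNetwork) -> dict[str, int]:
    """Deterministic greedy-modularity partition used as the fixed reference."""
    comms = nx.community.greedy_modularity_communities(net.graph, weight=None)
    label: dict[str, int] = {}
    for ci, comm in enumerate(sorted(comms, key=lambda c: sorted(c)[0])):
        for g in comm:
            label[g] = ci
    return label


def randomize_preserve_modularity(
    net: GeneNetwork, rng: np.random.Generator, swaps_per_edge: int = 10
) -> GeneNetwork:
    """Double-edge swaps restricted to matching community-pair labels.

    A fixed partition is detected once (greedy modularity maximization);
    swapping only edge pairs that connect the same (unordered) pair of
    communities — with endpoints aligned by community — preserves node
    degrees and every within/between-community edge count, hence the
    partition's Newman modularity Q exactly.
    """
    _require_undirected(net)
    label = detect_communities(net)
    edges = []
    for u, v, _ in net.edges():
        # orient so the first endpoint carries the smaller community label
        if (label[u], u) <= (label[v], v):
            edges.append((u, v))
        else:
            edges.append((v, u))

    def pair_label(e):
        u, v = e
        return (label[u], label[v])

    labels = [pair_label(e) for e in edges]

    def allowed(a: int, b: int) -> bool:
        return labels[a] == labels[b]

    out = _double_edge_swaps(edges, rng, swaps_per_edge * len(edges), allowed=allowed)
    return _rebuild(net, out, rng)


def perturb_edges(
    net: GeneNetwork,
    fraction: float,
    direction: str,
    rng: np.random.Generator,
) -> GeneNetwork:
    """Add or remove round(fraction * |E|) edges (minimum 1).

    Added edges connect previously non-adjacent node pairs (new
    interactions only) and get weights resampled from the original
    weight distribution.
    """
    _require_undirected(net)
    if direction not in ("add", "remove"):
        raise ValueError("direction must be 'add' or 'remove'")
    m = max(1, round(fraction * net.n_edges))
    nodes = net.nodes
    edges = list(net.edges())
    if direction == "remove":
        keep = set(range(len(edges))) - set(
            rng.choice(len(edges), size=min(m, len(edges)), replace=False)
        )
        return GeneNetwork(
            [edges[i] for i in sorted(keep)], nodes=nodes, directed=False
        )
    # add
    n = len(nodes)
    max_edges = n * (n - 1) // 2
    if max_edges - net.n_edges < m:
        raise ValueError("not enough non-adjacent pairs to add the requested edges")
    existing = {frozenset((u, v)) for u, v, _ in edges}
    new_pairs = []
    tries = 0
    while len(new_pairs) < m:
        tries += 1
        if tries > 1000 * m:
            raise ValueError("could not sample enough non-adjacent pairs")
        i, j = rng.choice(n, size=2, replace=False)
        key = frozenset((i, j))
        if frozenset((nodes[i], nodes[j])) in existing:
            continue
        existing.add(frozenset((nodes[i], nodes[j])))
        new_pairs.append((nodes[i], nodes[j]))
    weights = resample_weights(net.confidences() or [1.0], m, rng)
    return GeneNetwork(
        edges + [(u, v, w) for (u, v), w in zip(new_pairs, weights)],
        nodes=nodes,
        directed=False,
    )


def randomize(
    net: GeneNetwork, config: RandomizationConfig, rng: np.random.Generator
) -> GeneNetwork:
    """Dispatch one randomization replicate according to ``config.method``."""
    if config.method == "total_rewire":
        return randomize_total_rewire(net, rng)
    if config.method == "preserve_degree":
        return randomize_preserve_degree(net, rng)
    if config.method == "preserve_modularity":
        return randomize_preserve_modularity(net, rng)
    if config.method == "add_fraction":
        return perturb_edges(net, config.fraction, "add", rng)
    if config.method == "remove_fraction":
        return perturb_edges(net, config.fraction, "remove", rng)
    raise ValueError(f"unknown randomization method {config.method!r}")


def normality_chi2(samples, n_bins: int = 10) -> tuple[float, float]:
    """Chi-square goodness of fit of samples against a fitted normal.

    Fits by sample mean/std, forms ``n_bins`` equal-probability bins
    under the fitted normal, pools adjacent bins until all expected
    counts reach 5, and returns (chi2, p) with df = bins - 3 (the two
    fitted parameters plus the total). A smaller statistic means the
    samples look more normally distributed.
    """
    x = np.asarray(list(samples), dtype=float)
    if x.size < 30:
        raise ValueError("need at least 30 samples for the chi-square test")
    mu = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        import warnings

        warnings.warn("zero-variance samples: chi2 undefined, returning inf")
        return float("inf"), 0.0
    # equal-probability bin edges under the fitted normal
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    edges = sp_stats.norm.ppf(qs, loc=mu, scale=sd)
    observed = np.histogram(x, bins=np.concatenate(([-np.inf], edges, [np.inf])))[0]
    expected = np.full(n_bins, x.size / n_bins, dtype=float)

    obs, exp = list(observed.astype(float)), list(expected)
    # pool adjacent bins until every expected count is >= 5
    i = 0
    while i < len(exp):
        if exp[i] < 5 and len(exp) > 1:
            j = i + 1 if i + 1 < len(exp) else i - 1
            exp[j] += exp[i]
            obs[j] += obs[i]
            del exp[i], obs[i]
            i = 0
        else:
            i += 1
    obs_a, exp_a = np.array(obs), np.array(exp)
    chi2 = float(np.sum((obs_a - exp_a) ** 2 / exp_a))
    df = max(len(exp_a) - 3, 1)
    p = float(sp_stats.chi2.sf(chi2, df))
    return chi2, p
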