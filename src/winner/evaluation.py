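"""Assessment procedures: retrieval metrics, directed-layer analysis,
ranking comparisons, and pathway-level assignment.

Retrieval of held-out genes is scored by precision, recall and F1
against a reference update set.  Directed networks are stratified into
layers by condensing strongly connected components (a regulatory cycle
acts as one unit) and breadth-first search from the source components;
low layers hold master regulators, high layers downstream effectors.
Rankings are compared by Pearson correlation against classical
centralities and PageRank.  Pathway-to-pathway regulatory networks are
assigned real-valued levels by a spine-and-offset procedure, and the
level of the pathways newly enriched in exponentially growing top-gene
bins is correlated with the bin exponent.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .network import GeneNetwork

__all__ = [
    "RetrievalResult",
    "LayerAssignment",
    "precision_recall_f1",
    "bfs_layers",
    "percentile_by_layer",
    "baseline_rankers",
    "compare_rankings",
    "pathway_levels",
    "bin_level_correlation",
]


@dataclass(frozen=True)
class RetrievalResult:
    predicted: frozenset
    reference: frozenset
    precision: float
    recall: float
    f1: float


@dataclass
class LayerAssignment:
    """Gene -> integer layer (>= 1); genes in a collapsed cycle share one."""

    gene_layer: dict[str, int]
    groups: list[frozenset]

    def layer(self, gene: str) -> int:
        return self.gene_layer[gene]


def precision_recall_f1(E, U) -> RetrievalResult:
    """precision = |E∩U|/|E|, recall = |E∩U|/|U|, F1 their harmonic mean."""
    E, U = frozenset(E), frozenset(U)
    hit = len(E & U)
    precision = hit / len(E) if E else 0.0
    recall = hit / len(U) if U else 0.0
    denom = precision + recall
    f1 = 2.0 * precision * recall / denom if denom else 0.0
    return RetrievalResult(E, U, precision, recall, f1)


def bfs_layers(net: GeneNetwork) -> LayerAssignment:
    """Layer genes of a directed network by condensation + BFS.

    Strongly connected components with >= 2 genes are contracted to
    single super-nodes.  Components with no incoming edges form
    layer 1; every other component gets 1 + its shortest condensed-path
    distance from the nearest root.
    """
    if not net.directed:
        raise ValueError("layer assignment requires a directed network")
    g = net.graph
    condensed = nx.condensation(g)
    roots = [c for c in condensed.nodes if condensed.in_degree(c) == 0]
    dist = nx.multi_source_dijkstra_path_length(condensed, roots) if roots else {}
    gene_layer: dict[str, int] = {}
    groups: list[frozenset] = []
    for c in condensed.nodes:
        members = frozenset(condensed.nodes[c]["members"])
        groups.append(members)
        layer = 1 + int(dist.get(c, 0))
        for gene in members:
            gene_layer[gene] = layer
    return LayerAssignment(gene_layer=gene_layer, groups=groups)


def percentile_by_layer(results) -> dict[int, list[float]]:
    """Pool percentile values per layer across several ranked pathways.

    ``results`` is an iterable of (RankingResult, LayerAssignment)
    pairs; pooling in percentile space lets pathways of different sizes
    be aggregated into one boxplot.
    """
    pooled: dict[int, list[float]] = {}
    for result, layers in results:
        for gene, pct in result.percentiles.items():
            pooled.setdefault(layers.layer(gene), []).append(pct)
    return dict(sorted(pooled.items()))


def baseline_rankers(net: GeneNetwork) -> dict[str, dict[str, float]]:
    """Classical per-node scores used as comparison rankers.

    pagerank (damping 0.85, uniform teleport, confidence-weighted),
    degree, betweenness (normalized), eigenvector (power iteration,
    tol 1e-8), clustering_coefficient.
    """
    g = net.graph
    out: dict[str, dict[str, float]] = {}
    out["pagerank"] = nx.pagerank(g, alpha=0.85, weight="confidence")
    out["degree"] = {n: float(d) for n, d in g.degree()}
    out["betweenness"] = nx.betweenness_centrality(g, normalized=True)
    try:
        out["eigenvector"] = nx.eigenvector_centrality(
            g, max_iter=10_000, tol=1e-8, weight="confidence"
        )
    except nx.PowerIterationFailedConvergence as exc:
        raise RuntimeError(
            "eigenvector centrality failed to converge on this network"
        ) from exc
    ug = g.to_undirected() if net.directed else g
    out["clustering_coefficient"] = nx.clustering(ug)
    return out


def compare_rankings(
    a: dict[str, float], b: dict[str, float]
) -> tuple[float, float]:
    """Pearson correlation (with two-sided p) over the shared genes."""
    shared = sorted(set(a) & set(b))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes to correlate")
    x = np.array([a[g] for g in shared])
    y = np.array([b[g] for g in shared])
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance scores")
    r, p = sp_stats.pearsonr(x, y)
    return float(r), float(p)


# ----------------------------------------------------------------------
# pathway-level assignment


def _longest_shortest_path(g: nx.DiGraph) -> list[str]:
    """Deterministic longest finite shortest path (spine).

    Ties broken lexicographically on (source, target); the path itself
    follows lexicographically smallest successors.
    """
    best: tuple[int, str, str] | None = None
    lengths = dict(nx.all_pairs_shortest_path_length(g))
    for u in sorted(g.nodes):
        for v in sorted(g.nodes):
            if u == v:
                continue
            d = lengths.get(u, {}).get(v)
            if d is None:
                continue
            key = (-d, u, v)
            if best is None or key < best:
                best = key
    if best is None:
        return [sorted(g.nodes)[0]]
    _, src, dst = best
    # deterministic BFS path reconstruction with sorted neighbor order
    target_d = lengths[src][dst]
    path = [src]
    cur = src
    for step in range(target_d):
        nxts = sorted(
            n
            for n in g.successors(cur)
            if lengths.get(n, {}).get(dst, np.inf) == target_d - step - 1
        )
        cur = nxts[0]
        path.append(cur)
    return path


def pathway_levels(relations: nx.DiGraph | GeneNetwork) -> dict[str, float]:
    """Assign real-valued levels to pathways in a regulatory network.

    Procedure: (1) all-pairs shortest paths; (2) the longest shortest
    path forms an upstream-to-downstream spine numbered 1..n;
    (3) unassigned pathways get levels offset from assigned ones by
    shortest directed distance (a pathway upstream of an assigned one
    subtracts its distance, downstream adds); (4) pathways reached from
    several assigned ones take the average; (5) repeat until all are
    assigned.  Disconnected remainders restart with a fresh spine.
    """
    g = relations.graph if isinstance(relations, GeneNetwork) else relations
    if g.number_of_nodes() == 0:
        raise ValueError("empty pathway network")
    if not g.is_directed():
        raise ValueError("pathway levels require a directed relation network")

    lengths = dict(nx.all_pairs_shortest_path_length(g))
    levels: dict[str, float] = {}
    spine = _longest_shortest_path(g)
    for i, p in enumerate(spine, start=1):
        levels[p] = float(i)

    unassigned = set(g.nodes) - set(levels)
    while unassigned:
        proposals: dict[str, list[float]] = {}
        for p in unassigned:
            for q, lq in levels.items():
                d_up = lengths.get(p, {}).get(q)  # p upstream of q
                if d_up is not None:
                    proposals.setdefault(p, []).append(lq - d_up)
                d_down = lengths.get(q, {}).get(p)  # p downstream of q
                if d_down is not None:
                    proposals.setdefault(p, []).append(lq + d_down)
        if not proposals:
            # disconnected remainder: start a new spine inside it
            sub = g.subgraph(sorted(unassigned)).copy()
            spine = _longest_shortest_path(sub)
            for i, p in enumerate(spine, start=1):
                levels[p] = float(i)
            unassigned -= set(spine)
            continue
        for p, vals in proposals.items():
            levels[p] = float(np.mean(vals))
        unassigned -= set(proposals)
    return levels


def bin_level_correlation(
    ranked_genes,
    gene_to_pathway: dict[str, set],
    levels: dict[str, float],
    max_exponent: int,
) -> tuple[float, pd.DataFrame]:
    """Correlate pathway level with exponential top-gene bin index.

    For x = 1..max_exponent the top 2^x genes' pathway set, minus the
    pathways already seen in smaller bins, gives the *add-on* pathways
    of bin x.  Pairs (x, level of each add-on pathway) feed a Pearson
    correlation.  Returns (r, table of bin/pathway/level rows).
    """
    ranked_genes = list(ranked_genes)
    if not ranked_genes:
        raise ValueError("empty ranked gene list")
    seen: set = set()
    rows = []
    for x in range(1, max_exponent + 1):
        top = ranked_genes[: 2**x]
        paths: set = set()
        for g in top:
            paths |= set(gene_to_pathway.get(g, ()))
        addon = paths - seen
        seen |= paths
        for p in sorted(addon):
            if p in levels:
                rows.append({"bin_exponent": x, "pathway": p, "level": levels[p]})
    if not rows:
        raise ValueError("no add-on pathways in any bin: correlation undefined")
    table = pd.DataFrame(rows)
    if table["level"].nunique() < 2 or table["bin_exponent"].nunique() < 2:
        raise ValueError("zero-variance bins or levels: correlation undefined")
    r, _ = sp_stats.pearsonr(table["bin_exponent"], table["level"])
    return float(r), table
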