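"""Weighted gene-gene interaction networks and seed sets.

The central container is :class:`GeneNetwork`, a thin validated wrapper
around a :class:`networkx.Graph` (or :class:`~networkx.DiGraph` when the
network carries regulatory direction).  Every edge carries a confidence
score ``c(j, i)`` in ``[0, 1]`` expressing the strength of the evidence
for the interaction; interactome databases such as STRING and HAPPI ship
such scores, and when a source provides none the confidence defaults
to 1.  For a directed network the edge ``source -> target`` means
"source regulates target".

Per-node aggregates used by the scoring engine live in
:class:`NodeStats`: ``w(i)`` is the summed confidence of the node's
interactions under a stated mode, ``I(i)`` the interaction count under
that mode, and ``W(i)`` the summed confidence of *all* the node's
interactions in the global interaction collection (used by the
expansion score, where it deliberately differs from ``w``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "SeedSet",
    "NodeStats",
    "read_edge_table",
    "read_seed_list",
    "node_stats",
    "induced_subnetwork",
    "write_scores",
]

VALID_MODES = ("undirected", "upstream", "downstream")


class GeneNetwork:
    """A weighted, optionally directed, gene-gene interaction network.

    Gene identifiers are opaque, case-sensitive strings.  Invariants
    enforced at construction: no self-loops, no duplicate node pairs
    (duplicates merged keeping the maximum confidence), and every
    confidence in ``[0, 1]``.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str, float]] = (),
        nodes: Iterable[str] = (),
        directed: bool = False,
    ) -> None:
        g: nx.Graph = nx.DiGraph() if directed else nx.Graph()
        g.add_nodes_from(str(n) for n in nodes)
        n_loops = 0
        for u, v, c in edges:
            u, v = str(u), str(v)
            c = float(c)
            if not 0.0 <= c <= 1.0:
                raise ValueError(
                    f"confidence {c!r} for edge {u}-{v} outside [0, 1]"
                )
            if u == v:
                n_loops += 1
                continue
            if g.has_edge(u, v):
                # duplicate pair: keep the strongest evidence
                g[u][v]["confidence"] = max(g[u][v]["confidence"], c)
            else:
                g.add_edge(u, v, confidence=c)
        if n_loops:
            logger.info("dropped %d self-loop(s)", n_loops)
        self._g = g
        self.directed = bool(directed)

    # ------------------------------------------------------------------
    # construction helpers
    @classmethod
    def from_graph(cls, g: nx.Graph, directed: bool | None = None) -> "GeneNetwork":
        """Wrap an existing networkx graph whose edges carry ``confidence``."""
        directed = g.is_directed() if directed is None else directed
        net = cls(directed=directed)
        edges = (
            (u, v, data.get("confidence", 1.0)) for u, v, data in g.edges(data=True)
        )
        return cls(edges=edges, nodes=g.nodes, directed=directed)

    # ------------------------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        """The underlying networkx graph (edges carry ``confidence``)."""
        return self._g

    @property
    def nodes(self) -> list[str]:
        return list(self._g.nodes)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for u, v, data in self._g.edges(data=True):
            yield u, v, data["confidence"]

    def confidences(self) -> list[float]:
        return [data["confidence"] for _, _, data in self._g.edges(data=True)]

    def has_node(self, gene: str) -> bool:
        return self._g.has_node(gene)

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def confidence(self, u: str, v: str) -> float:
        return self._g[u][v]["confidence"]

    def degree(self, gene: str) -> int:
        """Number of distinct interactions of ``gene`` (total degree)."""
        return self._g.degree(gene)

    def neighbors(self, gene: str) -> set[str]:
        if self.directed:
            return set(self._g.successors(gene)) | set(self._g.predecessors(gene))
        return set(self._g.neighbors(gene))

    def __contains__(self, gene: str) -> bool:
        return self._g.has_node(gene)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneNetwork):
            return NotImplemented
        if self.directed != other.directed:
            return False
        if set(self.nodes) != set(other.nodes):
            return False
        return self._edge_dict() == other._edge_dict()

    def _edge_dict(self) -> dict:
        if self.directed:
            return {(u, v): c for u, v, c in self.edges()}
        return {frozenset((u, v)): c for u, v, c in self.edges()}

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "directed" if self.directed else "undirected"
        return f"<GeneNetwork {kind} |V|={self.n_nodes} |E|={self.n_edges}>"


@dataclass(frozen=True)
class SeedSet:
    """A non-empty, ordered, duplicate-free set of seed gene identifiers."""

    members: tuple[str, ...]

    def __init__(self, members: Iterable[str]) -> None:
        seen: dict[str, None] = {}
        for m in members:
            seen.setdefault(str(m), None)
        if not seen:
            raise ValueError("no seeds: a seed set must be non-empty")
        object.__setattr__(self, "members", tuple(seen))

    def __iter__(self) -> Iterator[str]:
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.members)

    def union(self, genes: Iterable[str]) -> "SeedSet":
        return SeedSet(list(self.members) + list(genes))


@dataclass(frozen=True)
class NodeStats:
    """Per-node aggregates under a stated mode.

    ``w``: summed incident confidence under the mode; ``I``: incident
    interaction count under the mode; ``W``: summed incident confidence
    in the global interaction collection irrespective of mode.
    """

    gene: str
    w: float
    I: int
    W: float


# ----------------------------------------------------------------------
# IO


def read_edge_table(
    path, directed: bool = False, default_confidence: float = 1.0
) -> GeneNetwork:
    """Read a TSV edge table (columns source/target[/confidence]) or SIF.

    SIF rows (``nodeA relation nodeB``) get confidence 1.0.  Missing
    confidences default to ``default_confidence``; duplicate pairs are
    merged keeping the maximum confidence; self-loops are dropped.
    """
    path = str(path)
    if path.endswith(".sif"):
        edges = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split()
                if len(parts) < 3:
                    raise ValueError(f"{path}:{ln}: malformed SIF row: {line!r}")
                a, _rel, bs = parts[0], parts[1], parts[2:]
                edges.extend((a, b, 1.0) for b in bs)
        return GeneNetwork(edges, directed=directed)

    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    if "source" not in cols or "target" not in cols:
        raise ValueError(
            f"{path}: expected columns 'source' and 'target', got {list(df.columns)}"
        )
    src, tgt = df[cols["source"]].astype(str), df[cols["target"]].astype(str)
    if src.isna().any() or tgt.isna().any():
        bad = int((src.isna() | tgt.isna()).idxmax()) + 2
        raise ValueError(f"{path}: malformed row near line {bad}")
    if "confidence" in cols:
        conf = pd.to_numeric(df[cols["confidence"]], errors="coerce")
        if conf.isna().any():
            bad = int(conf.isna().idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(f"{path}: malformed confidence near line {bad}")
        conf = conf.fillna(default_confidence)
    else:
        conf = pd.Series(default_confidence, index=df.index, dtype=float)
    bad = (conf < 0) | (conf > 1)
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise ValueError(f"{path}: confidence outside [0, 1] near line {line}")
    return GeneNetwork(zip(src, tgt, conf.astype(float)), directed=directed)


def read_seed_list(path) -> SeedSet:
    """Read a plain-text seed list: one identifier per line, ``#`` comments."""
    members = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            members.append(line)
    if not members:
        raise ValueError(f"no seeds found in {path}")
    return SeedSet(members)


def write_scores(result, path, significance=None) -> None:
    """Write a ranking result as TSV, ordered by rank then identifier.

    Columns: gene, score, rank, percentile, p_r, mu, sigma.  The
    significance columns are left empty unless a
    ``SignificanceResult``-like mapping is supplied.
    """
    rows = []
    for gene in result.scores:
        row = {
            "gene": gene,
            "score": result.scores[gene],
            "rank": result.ranks[gene],
            "percentile": result.percentiles[gene],
            "p_r": "",
            "mu": "",
            "sigma": "",
        }
        if significance is not None and gene in significance.p_r:
            row["p_r"] = significance.p_r[gene]
            row["mu"] = significance.mu[gene]
            row["sigma"] = significance.sigma[gene]
        rows.append(row)
    df = pd.DataFrame(rows).sort_values(["rank", "gene"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ----------------------------------------------------------------------
# graph operations


def node_stats(
    net: GeneNetwork,
    global_net: GeneNetwork | None = None,
    mode: str = "undirected",
) -> dict[str, NodeStats]:
    """Per-node ``w``, ``I`` under ``mode`` and ``W`` from the global network.

    ``upstream`` counts the relationships a gene regulates (out-edges);
    ``downstream`` the relationships in which it is regulated
    (in-edges).  ``W`` is always the node's total incident confidence in
    ``global_net`` (falling back to ``net`` itself when no global
    network is given), irrespective of mode.
    """
    if mode not in VALID_MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if mode != "undirected" and not net.directed:
        raise ValueError(f"mode {mode!r} requires a directed network")
    g = net.graph
    ref = global_net if global_net is not None else net

    stats: dict[str, NodeStats] = {}
    for gene in g.nodes:
        if mode == "undirected":
            inc = g.edges(gene, data=True) if not net.directed else list(
                g.out_edges(gene, data=True)
            ) + list(g.in_edges(gene, data=True))
        elif mode == "upstream":
            inc = g.out_edges(gene, data=True)
        else:  # downstream
            inc = g.in_edges(gene, data=True)
        inc = list(inc)
        w = sum(d["confidence"] for _, _, d in inc)
        I = len(inc)
        if ref.has_node(gene):
            rg = ref.graph
            if ref.directed:
                W = sum(
                    d["confidence"]
                    for _, _, d in list(rg.out_edges(gene, data=True))
                    + list(rg.in_edges(gene, data=True))
                )
            else:
                W = sum(d["confidence"] for _, _, d in rg.edges(gene, data=True))
        else:
            W = w
        stats[gene] = NodeStats(gene=gene, w=w, I=I, W=W)
    return stats


def induced_subnetwork(net: GeneNetwork, genes: Iterable[str]) -> GeneNetwork:
    """Subnetwork on ``genes``: edges with both endpoints retained.

    Genes absent from ``net`` are retained as isolated nodes (with a
    logged warning) so that seed lists referring to unknown genes still
    produce a rankable network.
    """
    genes = {str(g) for g in genes}
    missing = genes - set(net.nodes)
    if missing:
        logger.warning(
            "%d gene(s) not in the network retained as isolated nodes: %s",
            len(missing),
            ", ".join(sorted(missing)[:5]) + ("..." if len(missing) > 5 else ""),
        )
    keep = genes & set(net.nodes)
    sub = net.graph.subgraph(keep)
    edges = ((u, v, d["confidence"]) for u, v, d in sub.edges(data=True))
    return GeneNetwork(edges, nodes=genes, directed=net.directed)
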