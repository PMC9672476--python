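"""Deterministic synthetic network generators for testing and benchmarking.

Real interactome inputs (pathway gene sets plus weighted interactions
from curated databases) are emulated at desk scale by four generator
families:

* scale-free weighted networks (preferential attachment) standing in
  for protein-protein interaction collections;
* planted expansion modules — a dense module hidden in a sparse
  background with part of its membership withheld from the seeds,
  giving a ground-truth update set for retrieval benchmarks;
* layered regulatory DAGs whose construction layers are recoverable,
  for upstream/downstream ranking analyses;
* random regular graphs as symmetric test beds.

Every generator is a pure function of its seed.  The default weight
distribution is a symmetric beta law on [0, 1], emulating full-range
database confidence scores.  Benchmarks that emulate a
high-confidence subset (interactions kept only above a confidence
cutoff, 0.75 being a typical choice) pass an explicit ``min_weight``
floor, which rescales the law to [min_weight, 1].
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .network import GeneNetwork, SeedSet

__all__ = [
    "beta_weights",
    "point_weights",
    "make_scale_free_weighted",
    "plant_expansion_module",
    "make_layered_dag",
    "make_regular_graph",
]


def beta_weights(a: float = 2.0, b: float = 2.0, min_weight: float = 0.0):
    """Weight sampler: min_weight + (1 - min_weight) * Beta(a, b)."""
    if not 0.0 <= min_weight < 1.0:
        raise ValueError("min_weight must be in [0, 1)")

    def sample(rng: np.random.Generator, k: int) -> np.ndarray:
        return min_weight + (1.0 - min_weight) * rng.beta(a, b, size=k)

    return sample


def point_weights(value: float = 1.0):
    """Degenerate sampler: every interaction gets the same confidence."""

    def sample(rng: np.random.Generator, k: int) -> np.ndarray:
        return np.full(k, float(value))

    return sample


def _label(i: int, prefix: str = "G") -> str:
    return f"{prefix}{i + 1:04d}"


def make_scale_free_weighted(
    n: int, m: int, weight_dist=None, rng_seed: int = 0
) -> GeneNetwork:
    """Preferential-attachment network with (n - m) * m edges.

    Node labels are G0001..; identical seeds give identical networks.
    """
    if not n > m >= 1:
        raise ValueError("need n > m >= 1")
    weight_dist = weight_dist or beta_weights()
    rng = np.random.default_rng(rng_seed)
    g = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
    edges = sorted(g.edges())
    weights = weight_dist(rng, len(edges))
    return GeneNetwork(
        ((_label(u), _label(v), w) for (u, v), w in zip(edges, weights)),
        nodes=(_label(i) for i in range(n)),
    )


def plant_expansion_module(
    background: GeneNetwork,
    module_size: int,
    module_density: float,
    held_out: int,
    rng_seed: int = 0,
    weight_dist=None,
) -> tuple[GeneNetwork, SeedSet, set[str]]:
    """Embed a dense module in a background network and withhold part of it.

    ``module_size`` background nodes are chosen at random and wired
    into a module where each internal pair is connected with
    probability ``module_density`` (existing background edges between
    them are kept).  The seeds are the module minus ``held_out``
    random members; the withheld members are the ground-truth update
    set for retrieval evaluation.
    """
    if not module_size > held_out >= 1:
        raise ValueError("need module_size > held_out >= 1")
    if not 0.0 < module_density <= 1.0:
        raise ValueError("module_density must be in (0, 1]")
    if module_size > background.n_nodes:
        raise ValueError("module larger than the background network")
    weight_dist = weight_dist or beta_weights()
    rng = np.random.default_rng(rng_seed)
    nodes = background.nodes
    module = sorted(rng.choice(len(nodes), size=module_size, replace=False))
    module_genes = [nodes[i] for i in module]

    edges = list(background.edges())
    new_pairs = []
    for i in range(module_size):
        for j in range(i + 1, module_size):
            u, v = module_genes[i], module_genes[j]
            if background.has_edge(u, v) or background.has_edge(v, u):
                continue
            if rng.random() < module_density:
                new_pairs.append((u, v))
    weights = weight_dist(rng, len(new_pairs))
    edges += [(u, v, w) for (u, v), w in zip(new_pairs, weights)]
    net = GeneNetwork(edges, nodes=nodes)

    held_idx = rng.choice(module_size, size=held_out, replace=False)
    held = {module_genes[i] for i in held_idx}
    seeds = SeedSet(g for g in module_genes if g not in held)
    return net, seeds, held


def make_layered_dag(
    layers: int,
    width: int,
    p_forward: float = 0.5,
    rng_seed: int = 0,
    weight_dist=None,
) -> GeneNetwork:
    """Directed network with edges only from layer l to layer l + 1.

    Each node below the top layer is guaranteed at least one incoming
    edge, so breadth-first layering recovers the construction exactly.
    Labels are L{layer}N{index}.
    """
    if layers < 2 or width < 1:
        raise ValueError("need layers >= 2 and width >= 1")
    if not 0.0 < p_forward <= 1.0:
        raise ValueError("p_forward must be in (0, 1]")
    weight_dist = weight_dist or beta_weights()
    rng = np.random.default_rng(rng_seed)

    def name(layer: int, i: int) -> str:
        return f"L{layer}N{i + 1:02d}"

    pairs = []
    for layer in range(1, layers):
        for j in range(width):
            incoming = []
            for i in range(width):
                if rng.random() < p_forward:
                    incoming.append((name(layer, i), name(layer + 1, j)))
            if not incoming:
                i = int(rng.integers(width))
                incoming = [(name(layer, i), name(layer + 1, j))]
            pairs.extend(incoming)
    weights = weight_dist(rng, len(pairs))
    all_nodes = (name(l, i) for l in range(1, layers + 1) for i in range(width))
    return GeneNetwork(
        ((u, v, w) for (u, v), w in zip(pairs, weights)),
        nodes=all_nodes,
        directed=True,
    )


def make_regular_graph(n: int, k: int, rng_seed: int = 0) -> GeneNetwork:
    """Random k-regular simple graph, all confidences 1."""
    if (n * k) % 2 != 0 or not 0 <= k < n:
        raise ValueError("infeasible regular-graph parameters")
    g = nx.random_regular_graph(k, n, seed=rng_seed)
    return GeneNetwork(
        ((_label(u), _label(v), 1.0) for u, v in sorted(g.edges())),
        nodes=(_label(i) for i in range(n)),
    )
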