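"""Network expansion: hypergeometric candidate filtering and the
one-gene-at-a-time growth loop.

Candidates are the genes adjacent (in the global interaction
collection) to at least one currently ranked gene.  Two
over-representation tests gate admission:

* **Test 1** asks whether the candidate's interactions hit ranked genes
  more often than expected given how many genes are ranked overall:
  the upper hypergeometric tail with population N = all other genes,
  K = ranked genes, n = the candidate's neighbors, k = its ranked
  neighbors.
* **Test 2** compares the candidate against its degree-closest ranked
  gene ("matched seed"): drawing as many interactions as the candidate
  has from the matched seed's neighborhood (K of which touch ranked
  genes), how surprising is the candidate's ranked-neighbor count?
  When the candidate's degree exceeds the matched seed's, the roles of
  the two neighborhoods are swapped and the complementary tail is
  used.

A candidate passes only if both p-values fall below alpha (0.05 by
default); its expansion p-value is p_e = max(p1e, p2e).  Among passing
candidates, the one with the highest expansion score

    e(i) = sum over ranked neighbors j of c(i, j) * S(j) / W(j)

is added (W(j) is gene j's total incident confidence in the global
collection — deliberately not the within-ranked-set w(j), so heavily
connected seeds pass on proportionally less of their score).  The
ranked set is then re-ranked on its induced subnetwork and the loop
repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from .network import GeneNetwork, SeedSet, induced_subnetwork
from .ranking import RankingConfig, RankingResult, rank

__all__ = [
    "ExpansionCandidate",
    "candidate_pool",
    "hypergeom_upper_tail",
    "expansion_test1",
    "expansion_test2",
    "filter_candidates",
    "expansion_score",
    "expand",
]


@dataclass
class ExpansionCandidate:
    """One candidate's test results and expansion score."""

    gene: str
    degree_global: int
    seed_links: int
    matched_seed: str | None
    p1e: float
    p2e: float
    pe: float
    score: float = 0.0
    iteration_added: int | None = None


def candidate_pool(ranked, global_net: GeneNetwork) -> set[str]:
    """Genes adjacent to >= 1 ranked gene in the global collection,
    excluding the ranked genes themselves."""
    ranked_set = set(ranked)
    missing = ranked_set - set(global_net.nodes)
    if missing:
        import logging

        logging.getLogger(__name__).warning(
            "%d ranked gene(s) absent from the global network", len(missing)
        )
    pool: set[str] = set()
    for g in ranked_set & set(global_net.nodes):
        pool |= global_net.neighbors(g)
    return pool - ranked_set


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n).

    X counts successes when drawing n items without replacement from a
    population of N containing K successes.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"k={k} outside [0, min(n, K)={min(n, K)}]")
    return float(sp_stats.hypergeom.sf(k - 1, N, K, n))


def _ranked_links(gene: str, ranked_set: set[str], global_net: GeneNetwork) -> int:
    return len(global_net.neighbors(gene) & ranked_set)


def expansion_test1(candidate: str, ranked, global_net: GeneNetwork) -> float:
    """Enrichment of the candidate's interactions for ranked genes.

    Universe: every gene in the global collection except the candidate.
    A candidate with no interactions returns 1.0 by convention.
    """
    ranked_set = set(ranked)
    if candidate in ranked_set:
        raise ValueError(f"candidate {candidate!r} is already ranked")
    n = global_net.degree(candidate) if global_net.has_node(candidate) else 0
    if n == 0:
        return 1.0
    N = global_net.n_nodes - 1
    K = len(ranked_set & (set(global_net.nodes) - {candidate}))
    k = _ranked_links(candidate, ranked_set, global_net)
    return hypergeom_upper_tail(N, K, n, min(k, min(n, K)))


def match_seed(candidate: str, ranked, global_net: GeneNetwork) -> str:
    """Ranked gene with degree closest to the candidate's.

    Ties broken toward the larger degree, then lexicographically.
    """
    ranked_list = [g for g in ranked if global_net.has_node(g)]
    if not ranked_list:
        raise ValueError("no ranked genes present in the global network")
    cand_deg = global_net.degree(candidate) if global_net.has_node(candidate) else 0
    return min(
        ranked_list,
        key=lambda g: (abs(global_net.degree(g) - cand_deg), -global_net.degree(g), g),
    )


def expansion_test2(
    candidate: str, ranked, global_net: GeneNetwork
) -> tuple[float, str]:
    """Candidate enrichment relative to its degree-matched ranked gene.

    With g* the matched seed, deg the global degree and k(.) the
    ranked-neighbor count: when deg(candidate) <= deg(g*),
    p2e = P[X >= k(candidate)] for X ~ HG(N=deg(g*), K=k(g*),
    n=deg(candidate)).  When deg(candidate) > deg(g*) the two
    neighborhoods swap roles and the complementary tail
    1 - P[X <= k(candidate) - 1] under X ~ HG(N=deg(candidate),
    K=k(candidate), n=deg(g*)) is used, clipped to [0, 1].  A matched
    seed with no ranked links gives 1.0 (no reference enrichment).
    """
    ranked_set = set(ranked)
    g_star = match_seed(candidate, ranked_set, global_net)
    deg_c = global_net.degree(candidate) if global_net.has_node(candidate) else 0
    deg_s = global_net.degree(g_star)
    k_c = _ranked_links(candidate, ranked_set, global_net)
    # the matched seed's links to *other* ranked genes
    k_s = len(global_net.neighbors(g_star) & (ranked_set - {g_star}))
    if k_s == 0 or deg_c == 0:
        return 1.0, g_star
    if k_c == 0:
        return 1.0, g_star
    if deg_c <= deg_s:
        N, K, n, k = deg_s, k_s, deg_c, k_c
        if k > min(n, K):
            return 0.0, g_star  # more ranked links than any draw could contain
        return hypergeom_upper_tail(N, K, n, k), g_star
    # candidate's neighborhood becomes the population
    N, K, n = deg_c, k_c, deg_s
    p = float(sp_stats.hypergeom.sf(k_c - 1, N, K, n))
    return float(np.clip(p, 0.0, 1.0)), g_star


def filter_candidates(
    pool, ranked, global_net: GeneNetwork, alpha: float = 0.05
) -> list[ExpansionCandidate]:
    """Candidates with p1e < alpha AND p2e < alpha, annotated with
    p_e = max(p1e, p2e)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    ranked_set = set(ranked)
    out = []
    for gene in sorted(pool):
        p1 = expansion_test1(gene, ranked_set, global_net)
        p2, g_star = expansion_test2(gene, ranked_set, global_net)
        if p1 < alpha and p2 < alpha:
            out.append(
                ExpansionCandidate(
                    gene=gene,
                    degree_global=global_net.degree(gene)
                    if global_net.has_node(gene)
                    else 0,
                    seed_links=_ranked_links(gene, ranked_set, global_net),
                    matched_seed=g_star,
                    p1e=p1,
                    p2e=p2,
                    pe=max(p1, p2),
                )
            )
    return out


def expansion_score(
    candidate: str,
    ranked,
    scores: dict[str, float],
    global_net: GeneNetwork,
) -> float:
    """e = sum over ranked neighbors j of c(candidate, j) * S(j) / W(j)."""
    ranked_set = set(ranked)
    if not global_net.has_node(candidate):
        return 0.0
    g = global_net.graph
    e = 0.0
    for j in global_net.neighbors(candidate) & ranked_set:
        if global_net.directed:
            inc = list(g.out_edges(j, data=True)) + list(g.in_edges(j, data=True))
        else:
            inc = g.edges(j, data=True)
        W = sum(d["confidence"] for _, _, d in inc)
        if W <= 0:
            continue  # unreachable when j has a neighbor; guarded anyway
        c = (
            global_net.confidence(candidate, j)
            if global_net.has_edge(candidate, j)
            else global_net.confidence(j, candidate)
        )
        e += c * scores.get(j, 0.0) / W
    return e


def expand(
    seeds: SeedSet,
    global_net: GeneNetwork,
    rank_config: RankingConfig | None = None,
    alpha: float = 0.05,
    max_add: int = 10,
) -> tuple[RankingResult, list[ExpansionCandidate]]:
    """Iterative one-gene-at-a-time network expansion.

    Each iteration ranks the current gene set on its induced
    subnetwork, filters the adjacent candidates through both
    hypergeometric tests, and admits the single passing candidate with
    the highest expansion score (ties: smaller p_e, then
    lexicographic).  Stops when no candidate passes or ``max_add``
    genes have been added.  Returns the final ranking over
    seeds + added genes and the ledger of every added candidate.
    """
    if max_add < 0:
        raise ValueError("max_add must be >= 0")
    rank_config = rank_config or RankingConfig()
    current = list(seeds)
    ledger: list[ExpansionCandidate] = []

    subnet = induced_subnetwork(global_net, current)
    result = rank(subnet, global_net, rank_config)
    for iteration in range(1, max_add + 1):
        pool = candidate_pool(current, global_net)
        passing = filter_candidates(pool, current, global_net, alpha)
        if not passing:
            break
        for cand in passing:
            cand.score = expansion_score(
                cand.gene, current, result.scores, global_net
            )
        best = min(passing, key=lambda c: (-c.score, c.pe, c.gene))
        best.iteration_added = iteration
        ledger.append(best)
        current.append(best.gene)
        subnet = induced_subnetwork(global_net, current)
        result = rank(subnet, global_net, rank_config)
    return result, ledger
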