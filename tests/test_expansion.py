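import itertools
import math

import pytest

from winner import (
    GeneNetwork,
    RankingConfig,
    SeedSet,
    candidate_pool,
    expand,
    expansion_score,
    expansion_test1,
    expansion_test2,
    filter_candidates,
    hypergeom_upper_tail,
    fixtures,
)


def enumeration_upper_tail(N, K, n, k):
    """Brute-force P[X >= k]: enumerate every n-subset of N items, the
    first K of which are successes."""
    total = 0
    hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for x in draw if x < K) >= k:
            hits += 1
    return hits / total if total else 1.0


class TestHypergeomUpperTail:
    @pytest.mark.parametrize(
        "N,K,n,k,expected",
        [
            (10, 5, 2, 2, 10 / 45),
            (20, 5, 4, 2, 1205 / 4845),
            (10, 5, 2, 0, 1.0),
        ],
    )
    def test_known_values(self, N, K, n, k, expected):
        assert hypergeom_upper_tail(N, K, n, k) == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_for_small_populations(self):
        for N in range(1, 9):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(n, K) + 1):
                        assert hypergeom_upper_tail(N, K, n, k) == pytest.approx(
                            enumeration_upper_tail(N, K, n, k), abs=1e-10
                        )

    def test_monotone_nonincreasing_in_k(self):
        vals = [hypergeom_upper_tail(30, 12, 8, k) for k in range(9)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(5, 6, 2, 1)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(5, 2, 2, 3)


def star_with_ranked(n_ranked, n_other, cand_links_ranked, cand_links_other):
    """Global network: ranked genes R*, background genes B*, candidate X
    wired to the stated numbers of each; ranked genes interlinked in a chain."""
    edges = []
    ranked = [f"R{i}" for i in range(n_ranked)]
    other = [f"B{i}" for i in range(n_other)]
    edges += [(a, b, 1.0) for a, b in zip(ranked, ranked[1:])]
    edges += [(a, b, 1.0) for a, b in zip(other, other[1:])]
    edges += [("X", r, 1.0) for r in ranked[:cand_links_ranked]]
    edges += [("X", o, 1.0) for o in other[:cand_links_other]]
    return GeneNetwork(edges, nodes=ranked + other + ["X"]), SeedSet(ranked)


class TestCandidatePool:
    def test_star_leaves(self):
        net = GeneNetwork([("HUB", f"L{i}", 1.0) for i in range(5)])
        assert candidate_pool(["HUB"], net) == {f"L{i}" for i in range(5)}

    def test_everything_ranked_gives_empty_pool(self, triangle):
        assert candidate_pool(["A", "B", "C"], triangle) == set()

    def test_other_component_excluded(self):
        net = GeneNetwork([("A", "B", 1.0), ("C", "D", 1.0)])
        assert candidate_pool(["A"], net) == {"B"}


class TestExpansionTest1:
    def test_fully_seed_linked_candidate(self):
        # candidate X: all 3 neighbors ranked; universe 10 genes, 5 ranked
        net, seeds = star_with_ranked(5, 5, 3, 0)
        p = expansion_test1("X", seeds, net)
        assert p == pytest.approx(enumeration_upper_tail(10, 5, 3, 3), abs=1e-10)

    def test_no_seed_links_gives_one(self):
        net, seeds = star_with_ranked(4, 5, 0, 2)
        assert expansion_test1("X", seeds, net) == 1.0

    def test_isolated_candidate_gives_one(self):
        net = GeneNetwork([("A", "B", 1.0)], nodes=["A", "B", "X"])
        assert expansion_test1("X", ["A"], net) == 1.0

    def test_fully_ranked_universe_forced_to_one(self):
        net = GeneNetwork([("X", "A", 1.0), ("X", "B", 1.0), ("A", "B", 1.0)])
        assert expansion_test1("X", ["A", "B"], net) == 1.0

    def test_already_ranked_candidate_rejected(self, triangle):
        with pytest.raises(ValueError):
            expansion_test1("A", ["A", "B"], triangle)


class TestExpansionTest2:
    def test_small_case_matches_enumeration(self):
        # matched seed degree 4 with 2 ranked links; candidate degree 3
        # with 2 ranked links -> HG(N=4, K=2, n=3), P[X >= 2]
        edges = [
            ("S", "R1", 1.0), ("S", "R2", 1.0), ("S", "B1", 1.0), ("S", "B2", 1.0),
            ("X", "R1", 1.0), ("X", "R2", 1.0), ("X", "B1", 1.0),
        ]
        net = GeneNetwork(edges)
        ranked = ["S", "R1", "R2"]
        p, g_star = expansion_test2("X", ranked, net)
        assert g_star == "S"
        assert p == pytest.approx(enumeration_upper_tail(4, 2, 3, 2), abs=1e-10)

    def test_monotone_in_candidate_seed_links(self):
        net_hi, ranked_hi = star_with_ranked(5, 5, 3, 0)
        net_lo, ranked_lo = star_with_ranked(5, 5, 2, 1)
        p_hi, _ = expansion_test2("X", ranked_hi, net_hi)
        p_lo, _ = expansion_test2("X", ranked_lo, net_lo)
        assert p_hi <= p_lo

    def test_candidate_without_seed_links_gives_one(self):
        net, seeds = star_with_ranked(4, 6, 0, 3)
        p, _ = expansion_test2("X", seeds, net)
        assert p == 1.0

    def test_matched_seed_without_ranked_links_gives_one(self):
        net = GeneNetwork(
            [("S", "B1", 1.0), ("S", "B2", 1.0), ("X", "S", 1.0), ("X", "B1", 1.0)]
        )
        p, g_star = expansion_test2("X", ["S"], net)
        assert p == 1.0

    def test_swapped_branch_in_unit_interval(self):
        # candidate degree exceeds every ranked gene's degree
        edges = [("X", f"N{i}", 1.0) for i in range(8)] + [
            ("S", "N0", 1.0), ("S", "N1", 1.0), ("X", "S", 1.0)
        ]
        net = GeneNetwork(edges)
        p, g_star = expansion_test2("X", ["S", "N0", "N1"], net)
        assert g_star == "S"
        assert 0.0 <= p <= 1.0


class TestFilterCandidates:
    def test_and_rule_and_pe_annotation(self):
        net, seeds = star_with_ranked(6, 8, 4, 0)
        pool = candidate_pool(seeds, net)
        out = filter_candidates(pool, seeds, net, alpha=0.05)
        for cand in out:
            assert cand.p1e < 0.05 and cand.p2e < 0.05
            assert cand.pe == max(cand.p1e, cand.p2e)
            assert cand.seed_links <= cand.degree_global

    def test_empty_pool_gives_empty_list(self, triangle):
        assert filter_candidates(set(), ["A"], triangle) == []

    def test_invalid_alpha_rejected(self, triangle):
        with pytest.raises(ValueError):
            filter_candidates({"B"}, ["A"], triangle, alpha=0.0)


class TestExpansionScore:
    def test_hand_computed_value(self):
        # X-j1 (c=0.8), X-j2 (c=0.5); W(j1)=4, W(j2)=2 in the global net
        edges = [
            ("X", "j1", 0.8), ("X", "j2", 0.5),
            ("j1", "a", 1.0), ("j1", "b", 1.0), ("j1", "c", 1.0),
            ("j1", "d", 0.2),
            ("j2", "e", 1.0), ("j2", "f", 0.5),
        ]
        net = GeneNetwork(edges)
        assert math.isclose(
            sum(net.graph[n]["j1"]["confidence"] for n in net.neighbors("j1")), 4.0
        )
        e = expansion_score("X", ["j1", "j2"], {"j1": 2.0, "j2": 1.0}, net)
        assert e == pytest.approx(0.8 * 2.0 / 4.0 + 0.5 * 1.0 / 2.0)

    def test_no_ranked_neighbors_gives_zero(self):
        net = GeneNetwork([("X", "B", 1.0), ("A", "B", 1.0)])
        assert expansion_score("X", ["A"], {"A": 1.0}, net) == 0.0

    def test_linear_in_scores(self):
        net, seeds = star_with_ranked(4, 4, 3, 1)
        scores = {g: float(i + 1) for i, g in enumerate(seeds)}
        doubled = {g: 2 * s for g, s in scores.items()}
        assert expansion_score("X", seeds, doubled, net) == pytest.approx(
            2 * expansion_score("X", seeds, scores, net)
        )


class TestExpand:
    def test_max_add_zero_is_plain_ranking(self, scale_free):
        seeds = SeedSet(scale_free.nodes[:10])
        result, ledger = expand(seeds, scale_free, max_add=0)
        assert ledger == []
        assert set(result.scores) == set(seeds)

    def test_added_genes_passed_both_tests_when_added(self):
        bg = fixtures.make_scale_free_weighted(150, 2, rng_seed=31)
        net, seeds, held = fixtures.plant_expansion_module(
            bg, 18, 0.7, 8, rng_seed=32
        )
        result, ledger = expand(seeds, net, max_add=8)
        assert ledger, "expected at least one admitted candidate"
        for i, cand in enumerate(ledger, start=1):
            assert cand.iteration_added == i
            assert cand.p1e < 0.05 and cand.p2e < 0.05
            assert cand.pe == max(cand.p1e, cand.p2e)
            assert cand.gene in result.scores

    def test_deterministic(self):
        bg = fixtures.make_scale_free_weighted(120, 2, rng_seed=33)
        net, seeds, _ = fixtures.plant_expansion_module(bg, 15, 0.8, 6, rng_seed=34)
        r1, l1 = expand(seeds, net, max_add=5)
        r2, l2 = expand(seeds, net, max_add=5)
        assert [c.gene for c in l1] == [c.gene for c in l2]
        assert r1.scores == r2.scores

    def test_recovers_planted_module_members_first(self):
        bg = fixtures.make_scale_free_weighted(200, 2, rng_seed=35)
        net, seeds, held = fixtures.plant_expansion_module(
            bg, 20, 0.6, 10, rng_seed=36
        )
        _, ledger = expand(seeds, net, max_add=10)
        added = [c.gene for c in ledger]
        assert added, "expansion admitted nothing on the planted module"
        first_background = next(
            (i for i, g in enumerate(added) if g not in held), len(added)
        )
        assert all(g in held for g in added[:first_background])
        assert len(set(added) & held) >= len(added) // 2
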