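"""Hypergeometric enrichment, FDR, term networks and protein-property tests,
checked against direct combinatorial computation."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest

from ipcon.enrichment import (
    AnnotationMap, EnrichmentError, bh_significant, build_term_network,
    clan_rollup, collapse_repeats, filter_oversize, hypergeom_term_test,
    pick_representatives, property_tests, term_association_edges, run_term_tests,
)
from ipcon.synthetic_data import simulate_annotations


def tail_p_enriched(N, K, n, k):
    """Direct combinatorial summation of P(X >= k)."""
    total = math.comb(N, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j)
               for j in range(k, min(K, n) + 1)) / total


def tail_p_depleted(N, K, n, k):
    total = math.comb(N, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j)
               for j in range(max(0, n - (N - K)), k + 1)) / total


class TestOversizeFilter:
    def test_paper_scale_cluster_sizes(self):
        sizes = {"worm": 705, "fish": 398, "ok": 200, "small": 12}
        kept, removed = filter_oversize(sizes)
        assert set(removed) == {"worm", "fish"}
        assert set(kept) == {"ok", "small"}  # 200 kept: threshold is strict >


class TestHypergeometric:
    def _map(self, rng, n_genes=40, n_terms=6):
        genes = [f"g{i}" for i in range(n_genes)]
        pairs = []
        for t in range(n_terms):
            freq = rng.uniform(0.1, 0.6)
            for g in genes:
                if rng.random() < freq:
                    pairs.append((g, f"T{t}"))
        return AnnotationMap.from_pairs(pairs, universe=genes), genes

    def test_tails_match_direct_summation(self, rng):
        checked = 0
        while checked < 200:
            N = int(rng.integers(5, 61))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            genes = [f"g{i}" for i in range(N)]
            carriers = list(rng.choice(genes, size=K, replace=False))
            fg = frozenset(rng.choice(genes, size=n, replace=False))
            ann = AnnotationMap.from_pairs([(g, "T") for g in carriers], universe=genes)
            res = hypergeom_term_test("T", fg, ann)
            k = len(set(carriers) & fg)
            assert res.p_enriched == pytest.approx(tail_p_enriched(N, K, n, k), rel=1e-9)
            assert res.p_depleted == pytest.approx(tail_p_depleted(N, K, n, k), rel=1e-9)
            checked += 1

    def test_foreground_equals_universe(self, rng):
        ann, genes = self._map(rng)
        for term in ann.terms():
            res = hypergeom_term_test(term, frozenset(genes), ann)
            assert res.p_enriched == pytest.approx(1.0)

    def test_zero_foreground_count_depletion_closed_form(self):
        genes = [f"g{i}" for i in range(20)]
        ann = AnnotationMap.from_pairs([(g, "T") for g in genes[:5]], universe=genes)
        res = hypergeom_term_test("T", frozenset(genes[10:]), ann)
        assert res.fg_count == 0
        assert res.p_depleted == pytest.approx(
            math.comb(15, 10) / math.comb(20, 10), rel=1e-9)

    def test_absent_term_rejected(self, rng):
        ann, genes = self._map(rng)
        with pytest.raises(EnrichmentError):
            hypergeom_term_test("MISSING", frozenset(genes[:5]), ann)


class _FakeResult:
    def __init__(self, term, p):
        self.term, self.p_two_sided, self.significant = term, p, False


class TestBH:
    def _direct_stepup(self, ps, fdr):
        m = len(ps)
        order = sorted(range(m), key=lambda i: ps[i])
        k_max = 0
        for rank, i in enumerate(order, start=1):
            if ps[i] <= rank * fdr / m:
                k_max = rank
        sig = set(order[:k_max])
        return [i in sig for i in range(m)]

    @pytest.mark.parametrize("ps,fdr", [
        ([0.001, 0.02, 0.03, 0.5], 0.01),
        ([1.0, 1.0, 1.0], 0.01),
        ([0.0, 0.0], 0.01),
    ])
    def test_examples_match_direct_stepup(self, ps, fdr):
        results = [_FakeResult(f"T{i}", p) for i, p in enumerate(ps)]
        bh_significant(results, fdr)
        assert [r.significant for r in results] == self._direct_stepup(ps, fdr)

    def test_random_matches_direct_stepup(self, rng):
        for _ in range(50):
            ps = list(rng.uniform(size=int(rng.integers(1, 30))))
            results = [_FakeResult(f"T{i}", p) for i, p in enumerate(ps)]
            bh_significant(results, 0.05)
            assert [r.significant for r in results] == self._direct_stepup(ps, 0.05)


class TestAssociationNetwork:
    def test_identical_annotation_sets_mutual_edge(self):
        genes = [f"g{i}" for i in range(60)]
        fg = frozenset(genes[:15])
        pairs = [(g, t) for g in genes[:15] for t in ("A", "B")]
        pairs += [(g, "C") for g in genes]  # uninformative term
        ann = AnnotationMap.from_pairs(pairs, universe=genes)
        graph = term_association_edges(fg, ann, fdr=0.05)
        assert graph.has_edge("A", "B")

    def test_disjoint_strong_terms_no_edge(self):
        genes = [f"g{i}" for i in range(200)]
        fg = frozenset(genes[:40])
        pairs = [(g, "A") for g in genes[:20]]
        pairs += [(g, "B") for g in genes[20:40]]
        ann = AnnotationMap.from_pairs(pairs, universe=genes)
        graph = term_association_edges(fg, ann, fdr=0.05)
        assert {"A", "B"} <= set(graph.nodes)
        assert not graph.has_edge("A", "B")

    def test_matches_naive_per_exclusion_rerun(self, rng):
        genes = [f"g{i}" for i in range(80)]
        fg = frozenset(genes[:20])
        pairs = []
        for t in range(5):
            for g in genes:
                bias = 0.55 if (g in fg and t < 3) else 0.15
                if rng.random() < bias:
                    pairs.append((g, f"T{t}"))
        ann = AnnotationMap.from_pairs(pairs, universe=genes)
        graph = term_association_edges(fg, ann, fdr=0.1)
        sig = {r.term for r in run_term_tests(fg, ann, 0.1) if r.significant}
        expected = set()
        for a in sig:
            keep = set(genes) - ann.genes_with(a)
            sub = AnnotationMap.from_pairs([(g, t) for g, t in pairs if g in keep],
                                           universe=keep)
            still = {r.term for r in run_term_tests(fg & keep, sub, 0.1)
                     if r.significant}
            for b in sig - {a}:
                if b not in still:
                    expected.add(frozenset((a, b)))
        assert {frozenset(e) for e in graph.edges} == expected


class TestRepresentatives:
    def test_star_hub_selected(self):
        g = nx.star_graph(5)  # node 0 is the hub
        g = nx.relabel_nodes(g, {i: f"T{i}" for i in g.nodes})
        reps = pick_representatives(g)
        assert reps[0][0] == "T0" and len(reps[0][1]) == 5
        assert len(reps) == 1

    def test_isolated_edge_tie_break(self):
        g = nx.star_graph(5)
        g = nx.relabel_nodes(g, {i: f"T{i}" for i in g.nodes})
        g.add_edge("P1", "P2")
        reps = pick_representatives(g)
        assert [r[0] for r in reps] == ["T0", "P1"]

    def test_random_graph_matches_stepwise_simulation(self, rng):
        for _ in range(20):
            g = nx.gnp_random_graph(12, 0.25, seed=int(rng.integers(1 << 30)))
            g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
            reps = pick_representatives(g)
            # independent stepwise simulation
            work = g.copy()
            expected = []
            while work.nodes:
                deg = dict(work.degree())
                best = sorted(deg, key=lambda n: (-deg[n], n))[0]
                expected.append((best, frozenset(work.neighbors(best))))
                for n in [best, *list(work.neighbors(best))]:
                    work.remove_node(n)
            assert reps == expected

    def test_groups_partition_nodes(self, rng):
        g = nx.gnp_random_graph(15, 0.2, seed=99)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        reps = pick_representatives(g)
        covered = []
        for term, group in reps:
            covered.append(term)
            covered.extend(group)
        assert sorted(covered) == sorted(g.nodes)


class TestPfamHelpers:
    def test_clan_rollup(self):
        ann = AnnotationMap.from_pairs(
            [("g1", "PF00069"), ("g2", "PF99999"), ("g3", "PF00001"), ("g3", "PF00002")],
        )
        rolled = clan_rollup(ann, {"PF00069": "CL0016", "PF00001": "CL1", "PF00002": "CL1"})
        assert rolled.gene_terms["g1"] == frozenset({"CL0016"})
        assert rolled.gene_terms["g2"] == frozenset({"PF99999"})  # unmapped unchanged
        assert rolled.gene_terms["g3"] == frozenset({"CL1"})      # deduplicated

    @pytest.mark.parametrize("hits,repeats,expected,count", [
        (["A", "R", "R", "R", "B"], {"R"}, ["A", "R", "B"], 3),
        (["R", "A", "R"], {"R"}, ["R", "A", "R"], 3),
        ([], {"R"}, [], 0),
        (["A", "A"], set(), ["A", "A"], 2),  # non-repeat runs not collapsed
    ])
    def test_collapse_repeats(self, hits, repeats, expected, count):
        assert collapse_repeats(hits, repeats) == (expected, count)


class TestPropertyTests:
    def test_identical_sets(self):
        vals = {"length_aa": [100.0, 120.0, 140.0]}
        out = property_tests(vals, vals)
        assert out["length_aa"]["p"] == pytest.approx(1.0)
        assert out["length_aa"]["percent_difference"] == pytest.approx(0.0)

    def test_percent_difference(self):
        out = property_tests({"length_aa": [125.0] * 5}, {"length_aa": [100.0] * 5})
        assert out["length_aa"]["percent_difference"] == pytest.approx(25.0)


class TestPlantedRecovery:
    def test_planted_term_detected(self, rng):
        """5x planted term flagged at FDR 1% (10 seeded runs)."""
        hitcount = 0
        for seed in range(10):
            pairs, fg, universe = simulate_annotations(np.random.default_rng(seed))
            ann = AnnotationMap.from_pairs(pairs, universe=universe)
            results = run_term_tests(fg, ann, fdr=0.01)
            sig = {r.term for r in results if r.significant and r.direction == "enriched"}
            hitcount += "GO:7777777" in sig
        assert hitcount == 10
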