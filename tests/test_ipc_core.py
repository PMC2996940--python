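"""IPC scoring: projection, the score itself, spliceform maximization and
cluster-level aggregation, checked against exhaustive enumeration."""

from __future__ import annotations

import itertools
from statistics import fmean

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ipcon.gene_structures import IntronMark, ProteinRecord
from ipcon.ipc_core import (
    ClusterScorer, ScoringError, count_shared, ipc, pad_alignment,
    pairwise_identity, project_marks, score_pair,
)
from ipcon.ortholog_clusters import (
    ClusterMember, ExtendedCluster, OrthologCluster,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def rec(gene, tid, seq, marks, species="sp"):
    return ProteinRecord(species, gene, tid, seq,
                         tuple(IntronMark(i, 0) for i in sorted(marks)))


class TestProjection:
    def test_gap_shifts_columns(self):
        assert project_marks("MK-LS", [IntronMark(2, 0)]) == {3}

    def test_no_marks(self):
        assert project_marks("MK-LS", []) == frozenset()

    def test_mark_beyond_ungapped_length_raises(self):
        with pytest.raises(ScoringError):
            project_marks("MK--", [IntronMark(3, 0)])

    def test_random_gap_patterns_round_trip(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 40))
            seq = "".join(rng.choice(list(AA), size=n))
            n_gaps = int(rng.integers(0, 20))
            aligned = list(seq)
            for _ in range(n_gaps):
                aligned.insert(int(rng.integers(0, len(aligned) + 1)), "-")
            aligned = "".join(aligned)
            marks = [IntronMark(int(i), 0)
                     for i in rng.choice(n, size=min(n, 4), replace=False)]
            cols = project_marks(aligned, marks)
            residues = [c for c in aligned if c != "-"]
            for mark in marks:
                col = [c for c in cols
                       if len(aligned[:c].replace("-", "")) == mark.residue_index]
                assert len(col) == 1
                assert aligned[col[0]] == seq[mark.residue_index]


class TestIpcScore:
    @pytest.mark.parametrize("shared,na,nb,expected", [
        (2, 3, 2, 0.8),
        (1, 1, 1, 1.0),
        (4, 4, 4, 1.0),
        (0, 5, 0, 0.0),
        (0, 0, 3, 0.0),
    ])
    def test_fraction_formula(self, shared, na, nb, expected):
        assert ipc(shared, na, nb) == pytest.approx(expected)

    def test_both_intronless_undefined(self):
        assert ipc(0, 0, 0) is None

    def test_shared_exceeding_min_rejected(self):
        with pytest.raises(ScoringError):
            ipc(3, 2, 5)

    def test_jaccard_switch(self):
        assert ipc(2, 3, 2, formula="jaccard") == pytest.approx(2 / 3)

    @settings(max_examples=300, derandomize=True)
    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20))
    def test_symmetry_and_range(self, shared, extra_a, extra_b):
        na, nb = shared + extra_a, shared + extra_b
        v_ab = ipc(shared, na, nb)
        v_ba = ipc(shared, nb, na)
        if na + nb == 0:
            assert v_ab is None and v_ba is None
        else:
            assert v_ab == v_ba
            assert 0.0 <= v_ab <= 1.0
            assert (v_ab == 1.0) == (extra_a == 0 and extra_b == 0)

    def test_slide_rule(self):
        """A shift by one residue (3 nt) breaks sharing; a phase-only change
        (same codon, <= 2 nt slide) never does."""
        a = rec("ga", "t1", "MKLSVF", {2})
        shifted = rec("gb", "t1", "MKLSVF", {3})
        rephased = ProteinRecord("sp", "gc", "t1", "MKLSVF", (IntronMark(2, 2),))
        aln = {r.key: r.sequence for r in (a, shifted, rephased)}
        assert count_shared(project_marks(aln[a.key], a.marks),
                            project_marks(aln[shifted.key], shifted.marks)) == 0
        assert count_shared(project_marks(aln[a.key], a.marks),
                            project_marks(aln[rephased.key], rephased.marks)) == 1

    @pytest.mark.parametrize("a,b,expected", [
        ({3, 7}, {3, 9}, 1),
        ({1, 2, 3, 4}, {1, 2, 3, 4}, 4),
        ({1, 2}, {3, 4}, 0),
    ])
    def test_count_shared(self, a, b, expected):
        assert count_shared(a, b) == expected


class TestIdentity:
    @pytest.mark.parametrize("a,b,expected", [
        ("MKLS", "MKIS", 0.75),
        ("MKLS", "MKLS", 1.0),
        ("MK--", "--LS", 0.0),
        ("MK-S", "MKL-", 2 / 2),
    ])
    def test_examples(self, a, b, expected):
        assert pairwise_identity(a, b) == pytest.approx(expected)

    def test_length_mismatch_raises(self):
        with pytest.raises(ScoringError):
            pairwise_identity("MK", "MKL")


class TestScorePair:
    def test_best_spliceform_combination_chosen(self, rng):
        """3x2 spliceform grids equal exhaustive enumeration (100 grids)."""
        for _ in range(100):
            length = int(rng.integers(10, 30))
            def spliceforms(gene, n):
                out = []
                for i in range(n):
                    marks = set(int(x) for x in
                                rng.choice(length, size=int(rng.integers(0, 5)),
                                           replace=False))
                    seq = "".join(rng.choice(list(AA), size=length))
                    out.append(rec(gene, f"{gene}_t{i}", seq, marks))
                return out
            recs_a = spliceforms("ga", 3)
            recs_b = spliceforms("gb", 2)
            aln = {r.key: r.sequence for r in recs_a + recs_b}
            got = score_pair(recs_a, recs_b, aln, "o-o")
            # brute force over all combinations
            best = None
            for ra, rb in itertools.product(recs_a, recs_b):
                shared = len(ra.marked_residues & rb.marked_residues)
                v = ipc(shared, ra.n_introns, rb.n_introns)
                ident = pairwise_identity(ra.sequence, rb.sequence)
                key = (-1.0 if v is None else v, ident)
                if best is None or key > best[0]:
                    best = (key, v, ident)
            assert got.ipc == best[1]
            assert got.identity == pytest.approx(best[2])

    def test_all_undefined_flagged(self):
        a = rec("ga", "t1", "MKLS", set())
        b = rec("gb", "t1", "MKLS", set())
        aln = {a.key: a.sequence, b.key: b.sequence}
        assert score_pair([a], [b], aln, "o-o").ipc is None

    def test_missing_alignment_sequence_named(self):
        a = rec("ga", "t1", "MKLS", {1})
        b = rec("gb", "t1", "MKLS", {1})
        with pytest.raises(ScoringError, match="sp|gb|t1"):
            score_pair([a], [b], {a.key: a.sequence}, "o-o")


def make_cluster(members_a, members_b, seed_a, seed_b, cid="C0001"):
    members = [ClusterMember(g, "spA", 1.0 if g == seed_a else 0.5,
                             is_seed=(g == seed_a)) for g in members_a]
    members += [ClusterMember(g, "spB", 1.0 if g == seed_b else 0.5,
                              is_seed=(g == seed_b)) for g in members_b]
    return OrthologCluster(cid, "spA", "spB", seed_a, seed_b, 300.0, members)


class TestClusterScoring:
    def _setup(self, rng, n_a=3, n_b=2, with_cno=True):
        length = 30
        genes_a = [f"a{i}" for i in range(n_a)]
        genes_b = [f"b{i}" for i in range(n_b)]
        extra = ["ax", "bx"] if with_cno else []
        records = {}
        for g in genes_a + genes_b + extra:
            sp = "spA" if g.startswith("a") else "spB"
            marks = set(int(x) for x in rng.choice(length, size=4, replace=False))
            seq = "".join(rng.choice(list(AA), size=length))
            records[(sp, g)] = [ProteinRecord(sp, g, f"{g}_t1", seq,
                                              tuple(IntronMark(i, 0) for i in sorted(marks)))]
        cluster = make_cluster(genes_a, genes_b, "a0", "b0")
        ext = ExtendedCluster(cluster=cluster)
        for g in genes_a:
            ext.cno[g] = "bx" if with_cno else None
            ext.cni[g] = "ax" if with_cno else None
        for g in genes_b:
            ext.cno[g] = "ax" if with_cno else None
            ext.cni[g] = "bx" if with_cno else None
        aln = {r.key: r.sequence for recs in records.values() for r in recs}
        return records, cluster, ext, aln

    def test_one_to_one_structure(self, rng):
        records, _, ext, aln = self._setup(rng, n_a=1, n_b=1)
        summary, rows = ClusterScorer(records).score_extended_cluster(ext, aln)
        assert summary.n_pairs["o-o"] <= 1
        assert summary.n_pairs["i-i"] == 0
        assert not summary.is_multi and summary.consistent is None

    def test_pair_values_match_independent_recompute(self, rng):
        records, cluster, ext, aln = self._setup(rng)
        scorer = ClusterScorer(records)
        summary, rows = scorer.score_extended_cluster(ext, aln)

        def direct(ga, gb):
            ra = records[("spA" if ga.startswith("a") else "spB", ga)][0]
            rb = records[("spA" if gb.startswith("a") else "spB", gb)][0]
            shared = len(ra.marked_residues & rb.marked_residues)
            return ipc(shared, ra.n_introns, rb.n_introns)

        oo = [direct(a, b) for a in ["a0", "a1", "a2"] for b in ["b0", "b1"]]
        oo_defined = [v for v in oo if v is not None]
        assert summary.mean_ipc["o-o"] == pytest.approx(fmean(oo_defined))
        ii = [direct(*p) for p in
              itertools.chain(itertools.combinations(["a0", "a1", "a2"], 2),
                              itertools.combinations(["b0", "b1"], 2))]
        assert summary.mean_ipc["i-i"] == pytest.approx(
            fmean([v for v in ii if v is not None]))
        # o-cno: per o-o pair, mean of the two member-cno values
        ocno = []
        for a in ["a0", "a1", "a2"]:
            for b in ["b0", "b1"]:
                vals = [v for v in (direct(a, "bx"), direct(b, "ax")) if v is not None]
                if vals:
                    ocno.append(fmean(vals))
        assert summary.mean_ipc["o-cno"] == pytest.approx(fmean(ocno))
        # seed/max bookkeeping
        assert summary.seed_pair_ipc == direct("a0", "b0")
        assert summary.max_ortholog_pair_ipc == max(oo_defined)
        assert summary.consistent == (direct("a0", "b0") >= max(oo_defined))

    def test_member_order_permutation_invariant(self, rng):
        records, cluster, ext, aln = self._setup(rng)
        scorer = ClusterScorer(records)
        s1, _ = scorer.score_extended_cluster(ext, aln)
        shuffled = make_cluster(["a2", "a0", "a1"], ["b1", "b0"], "a0", "b0")
        ext2 = ExtendedCluster(cluster=shuffled, cno=ext.cno, cni=ext.cni)
        s2, _ = scorer.score_extended_cluster(ext2, aln)
        for t in ("o-o", "o-cno", "i-i", "i-cni"):
            if s1.mean_ipc[t] is None:
                assert s2.mean_ipc[t] is None
            else:
                assert s1.mean_ipc[t] == pytest.approx(s2.mean_ipc[t])

    def test_seed_tie_counts_as_consistent(self):
        # all sequences identical with identical marks: every pair ties at 1.0
        records = {}
        for g in ["a0", "a1", "b0"]:
            sp = "spA" if g.startswith("a") else "spB"
            records[(sp, g)] = [rec(g, f"{g}_t1", "MKLSVF", {1, 4}, species=sp)]
        cluster = make_cluster(["a0", "a1"], ["b0"], "a0", "b0")
        ext = ExtendedCluster(cluster=cluster,
                              cno={g: None for g in ["a0", "a1", "b0"]},
                              cni={g: None for g in ["a0", "a1", "b0"]})
        aln = {r.key: r.sequence for recs in records.values() for r in recs}
        summary, _ = ClusterScorer(records).score_extended_cluster(ext, aln)
        assert summary.is_multi and summary.consistent is True

    def test_spliceform_pool_maximization(self):
        """The re-added shorter spliceform can provide the best IPC."""
        a_long = rec("a0", "t1", "MKLSVFAA", {1})
        a_short = rec("a0", "t2", "MKLSVF", {1, 4})
        b = rec("b0", "t1", "MKLSVFAA", {1, 4}, species="spB")
        a_long = ProteinRecord("spA", "a0", "t1", a_long.sequence, a_long.marks)
        a_short = ProteinRecord("spA", "a0", "t2", a_short.sequence, a_short.marks)
        records = {("spA", "a0"): [a_long, a_short], ("spB", "b0"): [b]}
        cluster = make_cluster(["a0"], ["b0"], "a0", "b0")
        ext = ExtendedCluster(cluster=cluster, cno={"a0": None, "b0": None},
                              cni={"a0": None, "b0": None},
                              spliceform_pool={"a0": ["t2"]})
        aln = pad_alignment([a_long, a_short, b])
        summary, rows = ClusterScorer(records).score_extended_cluster(ext, aln)
        assert summary.mean_ipc["o-o"] == pytest.approx(1.0)  # via t2
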