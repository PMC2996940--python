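"""Intron position conservation (IPC) scoring through a multiple alignment.

Marked residues (codon-level intron positions) are projected onto alignment
columns; two sequences share an intron position when their marks land in the
same column.  Because a mark lower-cases the residue of the codon the intron
precedes or interrupts, same-column equality is exactly the same-codon
criterion (an intron may slide at most 2 nucleotides and still count as
conserved).

The IPC score of a pair is ``2 * shared / (n_A + n_B)`` by default (symmetric,
in [0, 1], equal to 1 iff the two mark sets coincide after projection); the
Jaccard form ``shared / (n_A + n_B - shared)`` is available as an alternative.
A pair of two intronless sequences has no defined IPC and is excluded from
averages; a one-sided intronless pair scores 0.

Four pair types are scored per extended cluster: ortholog-ortholog (o-o,
cross-species member pairs), inparalog-inparalog (i-i, within-species member
pairs), ortholog-closest non-ortholog (o-cno) and inparalog-closest
non-inparalog (i-cni).  When a gene has several spliceforms the combination
with the highest IPC is chosen; each o-o (i-i) pair contributes one o-cno
(i-cni) value, the mean over its two members' cno (cni) pairs where defined.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from statistics import fmean
from typing import Iterable, Literal, Mapping, Sequence

from .gene_structures import IntronMark, ProteinRecord
from .ortholog_clusters import ExtendedCluster

PairType = Literal["o-o", "o-cno", "i-i", "i-cni"]
PAIR_TYPES: tuple[PairType, ...] = ("o-o", "o-cno", "i-i", "i-cni")
IpcFormula = Literal["fraction", "jaccard"]

GAP_CHARS = frozenset("-.")


class ScoringError(ValueError):
    pass


def project_marks(aligned_sequence: str, marks: Iterable[IntronMark]) -> frozenset[int]:
    """Map marked residue indices to 0-based alignment column indices."""
    residue_to_column: list[int] = []
    for col, ch in enumerate(aligned_sequence):
        if ch not in GAP_CHARS:
            residue_to_column.append(col)
    columns = set()
    for mark in marks:
        if mark.residue_index >= len(residue_to_column):
            raise ScoringError(
                f"mark at residue {mark.residue_index} beyond ungapped length "
                f"{len(residue_to_column)}"
            )
        columns.add(residue_to_column[mark.residue_index])
    return frozenset(columns)


def count_shared(columns_a: frozenset[int] | set[int], columns_b: frozenset[int] | set[int]) -> int:
    """Number of intron positions conserved under the same-codon criterion."""
    return len(set(columns_a) & set(columns_b))


def ipc(shared: int, n_a: int, n_b: int, formula: IpcFormula = "fraction") -> float | None:
    """IPC score; ``None`` (undefined) when both sequences are intronless."""
    if shared > min(n_a, n_b):
        raise ScoringError(f"shared {shared} exceeds min({n_a}, {n_b})")
    if n_a + n_b == 0:
        return None
    if formula == "fraction":
        return 2.0 * shared / (n_a + n_b)
    if formula == "jaccard":
        return shared / (n_a + n_b - shared)
    raise ValueError(f"unknown IPC formula {formula!r}")


def pairwise_identity(aligned_a: str, aligned_b: str) -> float:
    """Identical residues over co-aligned (both non-gap) columns; 0 if none."""
    if len(aligned_a) != len(aligned_b):
        raise ScoringError(
            f"aligned lengths differ: {len(aligned_a)} vs {len(aligned_b)}"
        )
    matches = 0
    cols = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca in GAP_CHARS or cb in GAP_CHARS:
            continue
        cols += 1
        if ca.upper() == cb.upper():
            matches += 1
    return matches / cols if cols else 0.0


@dataclass
class PairScore:
    """Score of one gene pair (IPC-maximizing spliceform combination)."""

    id_a: str
    id_b: str
    pair_type: PairType
    introns_shared: int
    introns_seq_a: int
    introns_seq_b: int
    ipc: float | None
    identity: float
    gene_a: str = ""
    gene_b: str = ""
    cluster_id: str = ""

    @property
    def defined(self) -> bool:
        return self.ipc is not None


@dataclass
class ClusterSummary:
    cluster_id: str
    is_multi: bool
    n_members: int
    mean_ipc: dict[str, float | None] = field(default_factory=dict)
    mean_identity: dict[str, float | None] = field(default_factory=dict)
    n_pairs: dict[str, int] = field(default_factory=dict)
    seed_pair_ipc: float | None = None
    max_ortholog_pair_ipc: float | None = None
    consistent: bool | None = None
    min_seed_bootstrap: float | None = None


def _aligned(alignment: Mapping[str, str], record: ProteinRecord) -> str:
    try:
        return alignment[record.key]
    except KeyError:
        raise ScoringError(f"alignment is missing sequence {record.key}") from None


def score_pair(
    records_a: Sequence[ProteinRecord],
    records_b: Sequence[ProteinRecord],
    alignment: Mapping[str, str],
    pair_type: PairType,
    formula: IpcFormula = "fraction",
) -> PairScore:
    """Score a gene pair, maximizing IPC over spliceform combinations.

    Ties are broken by higher identity, then by lexicographic spliceform
    keys.  If every combination is undefined (both spliceforms intronless),
    the returned score has ``ipc=None`` and carries the highest-identity
    combination's identity.
    """
    if not records_a or not records_b:
        raise ScoringError("score_pair needs at least one spliceform per gene")
    best: PairScore | None = None
    best_rank: tuple[float, float] | None = None
    for rec_a, rec_b in itertools.product(
        sorted(records_a, key=lambda r: r.key), sorted(records_b, key=lambda r: r.key)
    ):
        aln_a, aln_b = _aligned(alignment, rec_a), _aligned(alignment, rec_b)
        cols_a = project_marks(aln_a, rec_a.marks)
        cols_b = project_marks(aln_b, rec_b.marks)
        shared = count_shared(cols_a, cols_b)
        value = ipc(shared, len(cols_a), len(cols_b), formula)
        identity = pairwise_identity(aln_a, aln_b)
        rank = (-1.0 if value is None else value, identity)
        if best_rank is None or rank > best_rank:
            best_rank = rank
            best = PairScore(
                id_a=rec_a.key, id_b=rec_b.key, pair_type=pair_type,
                introns_shared=shared, introns_seq_a=len(cols_a),
                introns_seq_b=len(cols_b), ipc=value, identity=identity,
                gene_a=rec_a.gene_id, gene_b=rec_b.gene_id,
            )
    assert best is not None
    return best


def _mean_or_none(values: Sequence[float]) -> float | None:
    return fmean(values) if values else None


class ClusterScorer:
    """Scores extended clusters given per-gene spliceform records and alignments.

    ``records_by_gene`` maps ``(species, gene_id)`` to the spliceforms usable
    for scoring (the retained longest spliceform, plus re-added shorter ones
    for cluster members).
    """

    def __init__(
        self,
        records_by_gene: Mapping[tuple[str, str], Sequence[ProteinRecord]],
        formula: IpcFormula = "fraction",
    ) -> None:
        self.records_by_gene = records_by_gene
        self.formula = formula
        self._species_of_gene: dict[str, str] = {}
        for (sp, gene) in records_by_gene:
            self._species_of_gene.setdefault(gene, sp)

    def _records(self, species: str, gene: str, pool: Mapping[str, Sequence[str]],
                 alignment: Mapping[str, str]) -> list[ProteinRecord]:
        recs = list(self.records_by_gene.get((species, gene), ()))
        if not recs:
            raise ScoringError(f"no protein record for gene {species}|{gene}")
        primary = min(recs, key=lambda r: (-r.length, r.spliceform_id))
        allowed = set(pool.get(gene, ()))
        usable = [r for r in recs if r is primary or r.spliceform_id in allowed]
        missing = [r.key for r in usable if r.key not in alignment]
        if missing:
            raise ScoringError(f"alignment is missing sequence {missing[0]}")
        return usable

    def score_extended_cluster(
        self,
        ext: ExtendedCluster,
        alignment: Mapping[str, str],
    ) -> tuple[ClusterSummary, list[PairScore]]:
        cluster = ext.cluster
        pool = ext.spliceform_pool
        sp_a, sp_b = cluster.species_a, cluster.species_b
        species_of = {m.gene_id: m.species for m in cluster.members}

        def recs(gene: str) -> list[ProteinRecord]:
            sp = species_of.get(gene) or self._species_of_gene.get(gene)
            if sp is None:
                raise ScoringError(f"unknown gene {gene}")
            return self._records(sp, gene, pool, alignment)

        def pair(gene_x: str, gene_y: str, ptype: PairType) -> PairScore:
            score = score_pair(recs(gene_x), recs(gene_y), alignment, ptype, self.formula)
            score.cluster_id = cluster.cluster_id
            return score

        members_a = [m.gene_id for m in cluster.members_of(sp_a)]
        members_b = [m.gene_id for m in cluster.members_of(sp_b)]

        rows: list[PairScore] = []
        by_type: dict[str, list[PairScore]] = {t: [] for t in PAIR_TYPES}

        # --- ortholog-ortholog: all cross-species member pairs -------------
        oo_pairs: dict[tuple[str, str], PairScore] = {}
        for ga, gb in itertools.product(members_a, members_b):
            ps = pair(ga, gb, "o-o")
            oo_pairs[(ga, gb)] = ps
            rows.append(ps)
            by_type["o-o"].append(ps)

        # --- inparalog-inparalog: within-species member pairs ---------------
        ii_pairs: dict[tuple[str, str], PairScore] = {}
        for group in (members_a, members_b):
            for ga, gb in itertools.combinations(group, 2):
                ps = pair(ga, gb, "i-i")
                ii_pairs[(ga, gb)] = ps
                rows.append(ps)
                by_type["i-i"].append(ps)

        # --- averaged cno / cni companions ---------------------------------
        def companion(parent: tuple[str, str], mapping: Mapping[str, str | None],
                      ptype: PairType) -> None:
            parts: list[PairScore] = []
            for gene in parent:
                other = mapping.get(gene)
                if other is not None:
                    parts.append(pair(gene, other, ptype))
            defined = [p for p in parts if p.defined]
            rows.extend(parts)
            if defined:
                merged = PairScore(
                    id_a="+".join(p.id_a for p in defined),
                    id_b="+".join(p.id_b for p in defined),
                    pair_type=ptype,
                    introns_shared=sum(p.introns_shared for p in defined),
                    introns_seq_a=sum(p.introns_seq_a for p in defined),
                    introns_seq_b=sum(p.introns_seq_b for p in defined),
                    ipc=fmean(p.ipc for p in defined),  # type: ignore[misc]
                    identity=fmean(p.identity for p in defined),
                    gene_a=parent[0], gene_b=parent[1],
                    cluster_id=cluster.cluster_id,
                )
                by_type[ptype].append(merged)

        for (ga, gb) in oo_pairs:
            companion((ga, gb), ext.cno, "o-cno")
        for (ga, gb) in ii_pairs:
            companion((ga, gb), ext.cni, "i-cni")

        # --- summary ---------------------------------------------------------
        summary = ClusterSummary(
            cluster_id=cluster.cluster_id,
            is_multi=cluster.is_multi,
            n_members=len(cluster.members),
            min_seed_bootstrap=cluster.min_seed_bootstrap,
        )
        for ptype in PAIR_TYPES:
            defined = [p.ipc for p in by_type[ptype] if p.ipc is not None]
            summary.mean_ipc[ptype] = _mean_or_none(defined)  # type: ignore[arg-type]
            summary.mean_identity[ptype] = _mean_or_none(
                [p.identity for p in by_type[ptype] if p.ipc is not None]
            )
            summary.n_pairs[ptype] = len(defined)

        seed_key = (cluster.seed_a, cluster.seed_b)
        if seed_key not in oo_pairs:
            seed_key = (cluster.seed_b, cluster.seed_a)
        seed_score = oo_pairs.get(seed_key)
        summary.seed_pair_ipc = seed_score.ipc if seed_score else None
        defined_oo = [p.ipc for p in oo_pairs.values() if p.ipc is not None]
        summary.max_ortholog_pair_ipc = max(defined_oo) if defined_oo else None
        if cluster.is_multi:
            if defined_oo:
                # an undefined (both-intronless) seed pair competes as 0.0
                seed_val = summary.seed_pair_ipc if summary.seed_pair_ipc is not None else 0.0
                summary.consistent = seed_val >= summary.max_ortholog_pair_ipc
            else:
                summary.consistent = None
        return summary, rows


# ---------------------------------------------------------------------------
# Trivial alignment for indel-free inputs
# ---------------------------------------------------------------------------

def pad_alignment(records: Sequence[ProteinRecord]) -> dict[str, str]:
    """Right-pad sequences with gaps to equal length.

    Only valid when the sequences are mutually alignable without internal
    gaps (e.g. simulated indel-free families whose shorter spliceforms are
    prefixes); a general aligner must be supplied for real data.
    """
    width = max(r.length for r in records)
    return {r.key: r.sequence + "-" * (width - r.length) for r in records}
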