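"""Two-species ortholog clustering and extended-cluster construction.

A simplified InParanoid-style procedure: seed ortholog pairs are the
bidirectional best hits between the two species (after coverage filtering),
and each species' inparalogs are the sequences scoring at least S — the seed
pair's similarity — against their own seed.  Seeds are processed greedily in
descending S with genes removed from the candidate pool once assigned, which
yields disjoint clusters without the full published conflict-resolution
machinery.  Bootstrap support values for seed assignments are consumed as
input (from an InParanoid-like table), never computed here.

Extended clusters add, for every member, the closest non-ortholog (cno, best
coverage-passing non-member hit in the other species) and closest
non-inparalog (cni, same in the member's own species), plus the member genes'
shorter spliceforms, prior to intron-position scoring.  Clusters of
mitochondrial genes are excluded outright (such sequences are intronless).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

DEFAULT_OVERLAP_CUTOFF = 0.5
DEFAULT_SEGMENT_CUTOFF = 0.25


class ClusterError(ValueError):
    pass


@dataclass(frozen=True)
class SimilarityHit:
    """One directed similarity search hit between two genes."""

    query_id: str
    subject_id: str
    query_species: str
    subject_species: str
    score: float
    query_coverage: float = 1.0
    max_segment_coverage: float = 1.0

    def __post_init__(self) -> None:
        if self.score <= 0:
            raise ClusterError(f"non-positive score for {self.query_id}->{self.subject_id}")
        for cov in (self.query_coverage, self.max_segment_coverage):
            if not 0.0 <= cov <= 1.0:
                raise ClusterError(f"coverage {cov} outside [0,1]")


def passes_coverage(
    hit: SimilarityHit,
    overlap_cutoff: float = DEFAULT_OVERLAP_CUTOFF,
    segment_cutoff: float = DEFAULT_SEGMENT_CUTOFF,
) -> bool:
    """Inclusive sequence-overlap and segment-coverage cutoffs (0.5 / 0.25)."""
    return (
        hit.query_coverage >= overlap_cutoff
        and hit.max_segment_coverage >= segment_cutoff
    )


@dataclass
class ClusterMember:
    gene_id: str
    species: str
    confidence: float
    is_seed: bool = False


@dataclass
class OrthologCluster:
    cluster_id: str
    species_a: str
    species_b: str
    seed_a: str
    seed_b: str
    score_s: float
    members: list[ClusterMember]
    seed_bootstrap_a: float | None = None
    seed_bootstrap_b: float | None = None

    @property
    def is_multi(self) -> bool:
        return len(self.members) > 2

    @property
    def member_ids(self) -> list[str]:
        return [m.gene_id for m in self.members]

    def members_of(self, species: str) -> list[ClusterMember]:
        return [m for m in self.members if m.species == species]

    @property
    def min_seed_bootstrap(self) -> float | None:
        vals = [b for b in (self.seed_bootstrap_a, self.seed_bootstrap_b) if b is not None]
        if len(vals) < 2:
            return None
        return min(vals)


@dataclass
class ExtendedCluster:
    cluster: OrthologCluster
    cno: dict[str, str | None] = field(default_factory=dict)
    cni: dict[str, str | None] = field(default_factory=dict)
    spliceform_pool: dict[str, list[str]] = field(default_factory=dict)

    @property
    def cluster_id(self) -> str:
        return self.cluster.cluster_id


class HitIndex:
    """Lookup structure over a similarity table.

    Keeps every directed hit (best score per ordered pair) and, per query,
    coverage-passing hit lists split into cross-species and within-species.
    """

    def __init__(
        self,
        hits: Iterable[SimilarityHit],
        overlap_cutoff: float = DEFAULT_OVERLAP_CUTOFF,
        segment_cutoff: float = DEFAULT_SEGMENT_CUTOFF,
    ) -> None:
        self.score: dict[tuple[str, str], float] = {}
        self.species: dict[str, str] = {}
        self._cross: dict[str, dict[str, float]] = defaultdict(dict)
        self._within: dict[str, dict[str, float]] = defaultdict(dict)
        for hit in hits:
            for gene, sp in ((hit.query_id, hit.query_species), (hit.subject_id, hit.subject_species)):
                known = self.species.setdefault(gene, sp)
                if known != sp:
                    raise ClusterError(f"gene {gene} listed under species {known} and {sp}")
            key = (hit.query_id, hit.subject_id)
            if hit.score > self.score.get(key, 0.0):
                self.score[key] = hit.score
            if not passes_coverage(hit, overlap_cutoff, segment_cutoff):
                continue
            table = self._within if hit.query_species == hit.subject_species else self._cross
            bucket = table[hit.query_id]
            if hit.score > bucket.get(hit.subject_id, 0.0):
                bucket[hit.subject_id] = hit.score

    def best_cross_hit(self, gene: str, exclude: frozenset[str] = frozenset()) -> tuple[str, float] | None:
        return self._best(self._cross.get(gene, {}), exclude)

    def best_within_hit(self, gene: str, exclude: frozenset[str] = frozenset()) -> tuple[str, float] | None:
        candidates = dict(self._within.get(gene, {}))
        candidates.pop(gene, None)
        return self._best(candidates, exclude)

    def within_candidates(self, gene: str) -> dict[str, float]:
        return self._within.get(gene, {})

    @staticmethod
    def _best(candidates: Mapping[str, float], exclude: frozenset[str]) -> tuple[str, float] | None:
        pool = [(s, sc) for s, sc in candidates.items() if s not in exclude]
        if not pool:
            return None
        # highest score; ties broken by lexicographically smallest subject id
        return min(pool, key=lambda it: (-it[1], it[0]))


def find_seed_pairs(
    hits: Iterable[SimilarityHit] | HitIndex,
    overlap_cutoff: float = DEFAULT_OVERLAP_CUTOFF,
    segment_cutoff: float = DEFAULT_SEGMENT_CUTOFF,
) -> list[tuple[str, str, float]]:
    """Bidirectional best hits between the two species.

    ``(a, b)`` is a seed pair iff b is a's best coverage-passing cross-species
    hit and vice versa; best-hit ties are broken by lexicographic subject id.
    S is the mean of the two directed scores.  Pairs are returned sorted by
    descending S, then by id.
    """
    index = hits if isinstance(hits, HitIndex) else HitIndex(hits, overlap_cutoff, segment_cutoff)
    seeds = []
    for gene in sorted(index._cross):
        best = index.best_cross_hit(gene)
        if best is None:
            continue
        partner, score_ab = best
        back = index.best_cross_hit(partner)
        if back is None or back[0] != gene:
            continue
        if gene < partner:  # emit each mutual pair once
            s = (score_ab + back[1]) / 2.0
            seeds.append((gene, partner, s))
    seeds.sort(key=lambda t: (-t[2], t[0], t[1]))
    return seeds


def add_inparalogs(
    seed: tuple[str, str, float],
    index: HitIndex,
    cluster_id: str = "C1",
    excluded: frozenset[str] = frozenset(),
) -> OrthologCluster:
    """Build the cluster around a seed pair.

    Per species independently, gene x joins iff its within-species score to
    the seed (x as query, seed as subject) is at least S.  Confidence is
    ``(sim(x, seed) - S) / (sim(seed, seed) - S)`` clamped to [0, 1]; seeds
    are fixed at 1.0.
    """
    gene_a, gene_b, s = seed
    sp_a, sp_b = index.species[gene_a], index.species[gene_b]
    if sp_a == sp_b:
        raise ClusterError(f"seed genes {gene_a},{gene_b} are from the same species")
    # keep the caller's (a, b) orientation but define species_a from seed_a
    members: list[ClusterMember] = []
    for seed_gene, sp in ((gene_a, sp_a), (gene_b, sp_b)):
        members.append(ClusterMember(seed_gene, sp, 1.0, is_seed=True))
        self_score = index.within_candidates(seed_gene).get(seed_gene)
        denom = None if self_score is None else self_score - s
        if denom is None or denom <= 0:
            logger.warning(
                "%s: self score of seed %s missing or <= S %.3g; "
                "inparalog confidences set to 0", cluster_id, seed_gene, s,
            )
            denom = None
        inpars = []
        # inparalog rule uses the score with the seed as subject (x -> seed)
        for gene in index._within:
            if gene == seed_gene or gene in excluded or index.species[gene] != sp:
                continue
            sim = index._within[gene].get(seed_gene)
            if sim is None or sim < s:
                continue
            conf = 0.0 if denom is None else max(0.0, min(1.0, (sim - s) / denom))
            inpars.append(ClusterMember(gene, sp, conf))
        inpars.sort(key=lambda m: (-m.confidence, m.gene_id))
        members.extend(inpars)
    return OrthologCluster(
        cluster_id=cluster_id,
        species_a=sp_a,
        species_b=sp_b,
        seed_a=gene_a,
        seed_b=gene_b,
        score_s=s,
        members=members,
    )


def build_clusters(
    hits: Iterable[SimilarityHit],
    overlap_cutoff: float = DEFAULT_OVERLAP_CUTOFF,
    segment_cutoff: float = DEFAULT_SEGMENT_CUTOFF,
) -> list[OrthologCluster]:
    """Greedy disjoint clustering: seeds in descending S, members assigned once."""
    index = hits if isinstance(hits, HitIndex) else HitIndex(hits, overlap_cutoff, segment_cutoff)
    seeds = find_seed_pairs(index)
    clusters: list[OrthologCluster] = []
    assigned: set[str] = set()
    n = 0
    for seed in seeds:
        gene_a, gene_b, _ = seed
        if gene_a in assigned or gene_b in assigned:
            continue
        n += 1
        cluster = add_inparalogs(seed, index, cluster_id=f"C{n:04d}", excluded=frozenset(assigned))
        clusters.append(cluster)
        assigned.update(cluster.member_ids)
    return clusters


def extend_cluster(
    cluster: OrthologCluster,
    index: HitIndex,
    organelle: Mapping[str, str] | None = None,
    spliceform_pool: Mapping[str, Sequence[str]] | None = None,
) -> ExtendedCluster | None:
    """Attach cno/cni and the members' shorter spliceforms; drop mitochondrial clusters.

    The cno (cni) of a member is its best coverage-passing hit in the other
    (own) species that is not a member of *this* cluster; membership in other
    clusters is no obstacle.  Returns ``None`` for mitochondrial clusters.
    """
    organelle = organelle or {}
    if any(organelle.get(g) == "mitochondrial" for g in cluster.member_ids):
        logger.info("%s: mitochondrial cluster excluded", cluster.cluster_id)
        return None
    member_set = frozenset(cluster.member_ids)
    ext = ExtendedCluster(cluster=cluster)
    for member in cluster.members:
        best_cno = index.best_cross_hit(member.gene_id, exclude=member_set)
        best_cni = index.best_within_hit(member.gene_id, exclude=member_set)
        ext.cno[member.gene_id] = best_cno[0] if best_cno else None
        ext.cni[member.gene_id] = best_cni[0] if best_cni else None
        if spliceform_pool:
            extra = list(spliceform_pool.get(member.gene_id, ()))
            if extra:
                ext.spliceform_pool[member.gene_id] = extra
    return ext


def extend_clusters(
    clusters: Sequence[OrthologCluster],
    index: HitIndex,
    organelle: Mapping[str, str] | None = None,
    spliceform_pool: Mapping[str, Sequence[str]] | None = None,
) -> list[ExtendedCluster]:
    out = []
    for cluster in clusters:
        ext = extend_cluster(cluster, index, organelle=organelle, spliceform_pool=spliceform_pool)
        if ext is not None:
            out.append(ext)
    return out
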