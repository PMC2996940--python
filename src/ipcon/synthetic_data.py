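"""Two-species gene-family simulator with known orthology and intron histories.

Each family descends from a single ancestral gene.  The main lineage
speciates at ``speciation_depth`` into one gene per species; optional
post-speciation duplications create inparalogs, and an optional
pre-speciation duplication at ``outparalog_depth`` creates an outparalog
lineage whose two post-speciation copies are the natural closest
non-ortholog / non-inparalog material.  Ancestral introns are inherited with
exponential survival ``exp(-loss_rate * t)`` per branch and new introns are
gained at protosplice-eligible sites (Poisson, phase 0).  Sequences evolve
indel-free by per-residue substitution, so the true alignment of a family is
trivial (shorter spliceforms are prefix truncations padded with gaps).

Duplicated copies can evolve at an accelerated rate
(``duplicate_rate_multiplier``), reflecting the relaxed constraint on young
duplicates; this is what makes the seed (retained) copy genuinely closest to
the other species' seed, so bidirectional-best-hit clustering and the
seed-consistency analysis have a meaningful ground truth.  "Confusable"
families duplicate immediately before the speciation at the neutral rate,
producing clusters whose seed ranking is ambiguous on purpose; they receive
low bootstrap support in the emitted cluster table and carry the planted
annotation term at elevated frequency.

Similarity scores are a monotone decreasing function of the
substitution-weighted path distance between two genes plus bounded symmetric
noise; only rank order matters to the clustering.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .gene_structures import IntronMark, ProteinRecord, marked_fasta_text
from .ortholog_clusters import ClusterMember, OrthologCluster, SimilarityHit

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

Mark = tuple[int, int]  # (residue index, phase)


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the simulator (all rates per unit time)."""

    n_families: int = 200
    species: tuple[str, str] = ("spA", "spB")
    speciation_depth: float = 1.0
    outparalog_depth: float = 2.0
    duplication_time: float = 0.4
    p_outparalog: float = 0.9
    p_inparalog_a: float = 0.5
    p_inparalog_b: float = 0.25
    p_confusable: float = 0.25
    confusable_duplication_fraction: float = 0.95  # of speciation_depth
    duplicate_rate_multiplier: float = 1.8
    n_ancestral_introns: int = 8
    protein_length: int = 200
    intron_loss_rate: float = 0.3
    intron_gain_rate: float = 0.01  # per eligible site per unit time
    protosplice_fraction: float = 0.1
    substitution_rate: float = 0.12
    family_rate_sigma: float = 0.4   # lognormal sigma of per-family sequence rate
    intron_rate_sigma: float = 0.3   # lognormal sigma of per-family intron turnover
    similarity_scale: float = 1000.0
    similarity_decay: float = 1.2
    similarity_noise: float = 0.02
    p_extra_spliceform: float = 0.2
    spliceform_truncation: float = 0.8
    p_mitochondrial: float = 0.05
    bootstrap_high: tuple[float, float] = (92.0, 100.0)
    bootstrap_low: tuple[float, float] = (50.0, 89.0)
    n_go_terms: int = 30
    planted_term: str = "GO:7777777"
    planted_fg_freq: float = 0.30
    planted_bg_freq: float = 0.06
    go_terms_per_gene: tuple[int, int] = (2, 5)
    n_pfam_domains: int = 15
    n_pfam_clans: int = 5

    def __post_init__(self) -> None:
        for rate in (self.intron_loss_rate, self.intron_gain_rate, self.substitution_rate):
            if rate < 0:
                raise ValueError("rates must be >= 0")
        for frac in (self.protosplice_fraction, self.p_outparalog, self.p_inparalog_a,
                     self.p_inparalog_b, self.p_confusable, self.p_mitochondrial,
                     self.p_extra_spliceform):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Scenario presets (the study conditions exercised by the analyses)
# ---------------------------------------------------------------------------

def headline_params(n_families: int = 200) -> SimParams:
    """Ancestral introns, moderate loss, outparalogs twice as deep as orthologs."""
    return SimParams(n_families=n_families)


def pure_loss_params(n_families: int = 500) -> SimParams:
    """1:1 families, pure intron loss; expected o-o IPC ~ exp(-loss_rate * 2 * depth / 2).

    Sized (20 ancestral introns, loss 0.2/unit) so the O(1/n) ratio-estimator
    bias of the IPC mean stays well below the Monte-Carlo noise floor.
    """
    return SimParams(
        n_families=n_families,
        p_outparalog=0.0, p_inparalog_a=0.0, p_inparalog_b=0.0,
        p_confusable=0.0, p_mitochondrial=0.0, p_extra_spliceform=0.0,
        n_ancestral_introns=20, intron_loss_rate=0.2, intron_gain_rate=0.0,
        similarity_noise=0.0, family_rate_sigma=0.0, intron_rate_sigma=0.0,
    )


def parallel_gain_control_params(n_families: int = 200) -> SimParams:
    """No ancestral introns; gains only, at a small protosplice set.

    The outparalog lineage splits exactly at the speciation (a root polytomy)
    and all rates are neutral, so the four family tips are exchangeable: any
    intron sharing is parallel gain and o-o / o-cno IPC are identically
    distributed.
    """
    return SimParams(
        n_families=n_families,
        outparalog_depth=1.0,  # == speciation_depth -> polytomy
        p_inparalog_a=0.0, p_inparalog_b=0.0,
        p_confusable=0.0, p_mitochondrial=0.0, p_extra_spliceform=0.0,
        duplicate_rate_multiplier=1.0,
        n_ancestral_introns=0, intron_loss_rate=0.0, intron_gain_rate=0.12,
        protosplice_fraction=0.08, similarity_noise=0.0,
        family_rate_sigma=0.0, intron_rate_sigma=0.0,
    )


# ---------------------------------------------------------------------------
# Intron and sequence evolution primitives
# ---------------------------------------------------------------------------

def evolve_introns(
    parent_marks: Iterable[Mark],
    branch_length: float,
    loss_rate: float,
    gain_rate: float,
    eligible_sites: Sequence[int],
    rng: np.random.Generator,
) -> frozenset[Mark]:
    """One branch of intron evolution.

    Each parent intron survives with probability ``exp(-loss_rate * t)``;
    the number of gains is Poisson with mean ``gain_rate * t * |eligible|``,
    placed (phase 0) at eligible sites whose codon is not already marked.
    """
    if loss_rate < 0 or gain_rate < 0:
        raise ValueError("rates must be >= 0")
    p_survive = math.exp(-loss_rate * branch_length)
    marks = {m for m in sorted(parent_marks) if rng.random() < p_survive}
    if gain_rate > 0 and eligible_sites:
        n_gain = rng.poisson(gain_rate * branch_length * len(eligible_sites))
        if n_gain:
            occupied = {res for res, _ in marks}
            free = sorted(set(eligible_sites) - occupied)
            if free:
                chosen = rng.choice(len(free), size=min(n_gain, len(free)), replace=False)
                marks.update((free[i], 0) for i in sorted(chosen))
    return frozenset(marks)


def evolve_sequence(
    parent: np.ndarray, branch_length: float, substitution_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-residue substitution to a uniformly chosen different residue."""
    p_sub = 1.0 - math.exp(-substitution_rate * branch_length)
    child = parent.copy()
    hit = rng.random(parent.size) < p_sub
    if hit.any():
        shifts = rng.integers(1, len(AA_ALPHABET), size=int(hit.sum()))
        child[hit] = (child[hit] + shifts) % len(AA_ALPHABET)
    return child


# ---------------------------------------------------------------------------
# Family trees
# ---------------------------------------------------------------------------

@dataclass
class _TipSpec:
    gene_id: str
    species: str
    role: str  # "seed" | "inparalog" | "outparalog"


@dataclass
class _Node:
    uid: int
    time: float  # before present
    children: list[tuple[float, float, "_Node"]] = field(default_factory=list)
    # (branch length in time units, rate multiplier, child)
    tip: _TipSpec | None = None


@dataclass
class TipState:
    spec: _TipSpec
    sequence: np.ndarray
    marks: frozenset[Mark]
    ancestors: dict[int, tuple[float, float]]  # node uid -> (node time, weighted path length to tip)


@dataclass
class FamilyTruth:
    family_id: str
    genes: dict[str, str]  # gene_id -> species
    roles: dict[str, str]  # gene_id -> seed | inparalog | outparalog
    relations: dict[frozenset, str]  # pair -> ortholog | inparalog | outparalog
    marks: dict[str, tuple[Mark, ...]]
    confusable: bool = False
    mitochondrial: bool = False
    consistent: bool | None = None  # seed pair attains max o-o IPC (multi only)

    def relation(self, gene_x: str, gene_y: str) -> str:
        return self.relations[frozenset((gene_x, gene_y))]


def _build_family_tree(params: SimParams, fam: str, confusable: bool,
                       has_out: bool, inpar: tuple[bool, bool]) -> _Node:
    sp_a, sp_b = params.species
    t_spec = params.speciation_depth
    depth_out = params.outparalog_depth
    mult = 1.0 if confusable else params.duplicate_rate_multiplier
    d_dup = (params.confusable_duplication_fraction * t_spec if confusable
             else params.duplication_time)
    counter = [0]

    def node(time: float, tip: _TipSpec | None = None) -> _Node:
        counter[0] += 1
        return _Node(uid=counter[0], time=time, tip=tip)

    def species_subtree(species: str, suffix_main: str, duplicated: bool) -> tuple[float, float, _Node]:
        """Lineage entering the speciation node; returns a child entry for it."""
        seed_tip = _TipSpec(f"{species}_{fam}{suffix_main}", species, "seed")
        if not duplicated:
            return (t_spec, 1.0, node(0.0, seed_tip))
        dup = node(d_dup)
        in_tip = _TipSpec(f"{species}_{fam}b", species, "inparalog")
        dup.children = [
            (d_dup, 1.0, node(0.0, seed_tip)),
            (d_dup, mult, node(0.0, in_tip)),
        ]
        return (t_spec - d_dup, 1.0, dup)

    def out_tip(species: str) -> _TipSpec:
        return _TipSpec(f"{species}_{fam}o", species, "outparalog")

    spec_main = node(t_spec)
    spec_main.children = [
        species_subtree(sp_a, "a", inpar[0]),
        species_subtree(sp_b, "a", inpar[1]),
    ]
    if not has_out:
        return spec_main
    if depth_out > t_spec:
        root = node(depth_out)
        spec_out = node(t_spec)
        spec_out.children = [
            (t_spec, 1.0, node(0.0, out_tip(sp_a))),
            (t_spec, 1.0, node(0.0, out_tip(sp_b))),
        ]
        root.children = [
            (depth_out - t_spec, 1.0, spec_main),
            (depth_out - t_spec, params.duplicate_rate_multiplier, spec_out),
        ]
        return root
    # polytomy: the outparalog lineage splits exactly at the speciation
    spec_main.children.append((t_spec, 1.0, node(0.0, out_tip(sp_a))))
    spec_main.children.append((t_spec, 1.0, node(0.0, out_tip(sp_b))))
    return spec_main


def simulate_family(
    params: SimParams, rng: np.random.Generator, family_index: int = 1,
) -> tuple[list[ProteinRecord], FamilyTruth]:
    """Simulate one family: protein records (with spliceforms) plus ground truth."""
    fam = f"F{family_index:04d}"
    mito = rng.random() < params.p_mitochondrial
    confusable = (not mito) and rng.random() < params.p_confusable
    has_out = rng.random() < params.p_outparalog
    inpar = (rng.random() < params.p_inparalog_a, rng.random() < params.p_inparalog_b)
    # gene families differ in evolutionary tempo: per-family lognormal factors
    # on the sequence rate and (independently) on intron turnover
    f_sub = float(np.exp(rng.normal(0.0, params.family_rate_sigma))) \
        if params.family_rate_sigma > 0 else 1.0
    f_intron = float(np.exp(rng.normal(0.0, params.intron_rate_sigma))) \
        if params.intron_rate_sigma > 0 else 1.0
    root = _build_family_tree(params, fam, confusable, has_out, inpar)

    length = params.protein_length
    seq0 = rng.integers(0, len(AA_ALPHABET), size=length)
    n_anc = 0 if mito else params.n_ancestral_introns
    anc_res = sorted(rng.choice(length, size=min(n_anc, length), replace=False)) if n_anc else []
    marks0 = frozenset((int(r), int(rng.integers(0, 3))) for r in anc_res)
    n_eligible = int(round(params.protosplice_fraction * length))
    eligible = sorted(int(r) for r in rng.choice(length, size=n_eligible, replace=False)) \
        if (n_eligible and not mito) else []

    tips: list[TipState] = []

    def walk(node: _Node, seq: np.ndarray, marks: frozenset[Mark],
             ancestors: dict[int, tuple[float, float]]) -> None:
        here = dict(ancestors)
        here[node.uid] = (node.time, 0.0)
        if node.tip is not None:
            tips.append(TipState(node.tip, seq, marks, here))
            return
        for branch_len, rate_mult, child in node.children:
            eff = branch_len * rate_mult
            child_seq = evolve_sequence(seq, eff, params.substitution_rate * f_sub, rng)
            child_marks = evolve_introns(
                marks, eff, params.intron_loss_rate * f_intron,
                params.intron_gain_rate * f_intron, eligible, rng,
            )
            walk(child, child_seq, child_marks,
                 {uid: (t, dist + eff) for uid, (t, dist) in here.items()})

    walk(root, seq0, marks0, {})
    tips.sort(key=lambda t: t.spec.gene_id)

    records: list[ProteinRecord] = []
    organelle = "mitochondrial" if mito else "nuclear"
    for tip in tips:
        seq_str = "".join(AA_ALPHABET[i] for i in tip.sequence)
        marks = tuple(IntronMark(res, phase) for res, phase in sorted(tip.marks))
        records.append(ProteinRecord(
            species=tip.spec.species, gene_id=tip.spec.gene_id,
            spliceform_id=f"{tip.spec.gene_id}_t1", sequence=seq_str,
            marks=marks, organelle=organelle,
        ))
        if rng.random() < params.p_extra_spliceform:
            cut = max(1, int(round(params.spliceform_truncation * length)))
            records.append(ProteinRecord(
                species=tip.spec.species, gene_id=tip.spec.gene_id,
                spliceform_id=f"{tip.spec.gene_id}_t2", sequence=seq_str[:cut],
                marks=tuple(m for m in marks if m.residue_index < cut),
                organelle=organelle,
            ))

    relations: dict[frozenset, str] = {}
    for i, x in enumerate(tips):
        for y in tips[i + 1:]:
            if "outparalog" in (x.spec.role, y.spec.role):
                rel = "outparalog"
            elif x.spec.species == y.spec.species:
                rel = "inparalog"
            else:
                rel = "ortholog"
            relations[frozenset((x.spec.gene_id, y.spec.gene_id))] = rel

    truth = FamilyTruth(
        family_id=fam,
        genes={t.spec.gene_id: t.spec.species for t in tips},
        roles={t.spec.gene_id: t.spec.role for t in tips},
        relations=relations,
        marks={t.spec.gene_id: tuple(sorted(t.marks)) for t in tips},
        confusable=confusable,
        mitochondrial=mito,
        consistent=_truth_consistency(tips, params),
    )
    truth._tips = tips  # type: ignore[attr-defined]  # kept for score computation
    truth._f_sub = f_sub  # type: ignore[attr-defined]
    return records, truth


def _truth_consistency(tips: Sequence[TipState], params: SimParams) -> bool | None:
    """Does the seed pair attain the highest codon-level IPC of all cross pairs?

    Computed from the true intron histories, so planted annotations can be
    tied to inconsistency by construction.  ``None`` for one-to-one families
    and for families where every cross pair is intron-free.
    """
    main = [t for t in tips if t.spec.role != "outparalog"]
    if len(main) <= 2:
        return None
    sp_a, sp_b = params.species

    def score(x: TipState, y: TipState) -> float | None:
        cx = {r for r, _ in x.marks}
        cy = {r for r, _ in y.marks}
        if not cx and not cy:
            return None
        return 2.0 * len(cx & cy) / (len(cx) + len(cy))

    seed_val: float | None = None
    best: float | None = None
    for x in main:
        if x.spec.species != sp_a:
            continue
        for y in main:
            if y.spec.species != sp_b:
                continue
            v = score(x, y)
            if v is None:
                continue
            best = v if best is None else max(best, v)
            if x.spec.role == "seed" and y.spec.role == "seed":
                seed_val = v
    if best is None:
        return None
    return (seed_val if seed_val is not None else 0.0) >= best


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    params: SimParams
    records: list[ProteinRecord]
    truths: list[FamilyTruth]
    hits: list[SimilarityHit]
    clusters: list[OrthologCluster]
    alignments: dict[str, dict[str, str]]  # cluster/family id -> key -> aligned seq
    go_annotations: list[tuple[str, str]]
    pfam_domains: list[tuple[str, int, str, bool]]  # gene, order, domain, repeat
    clan_map: dict[str, str]
    planted_term: str

    @property
    def focal_species(self) -> str:
        return self.params.species[0]


def _pair_distance(x: TipState, y: TipState) -> float:
    common = set(x.ancestors) & set(y.ancestors)
    # most recent common ancestor = the common node with the smallest age
    mrca = min(common, key=lambda uid: x.ancestors[uid][0])
    return x.ancestors[mrca][1] + y.ancestors[mrca][1]


def simulate_dataset(params: SimParams, seed: int) -> SyntheticDataset:
    """Simulate families and assemble every pipeline input, deterministically."""
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    truths: list[FamilyTruth] = []
    hits: list[SimilarityHit] = []
    clusters: list[OrthologCluster] = []
    alignments: dict[str, dict[str, str]] = {}

    for fam_idx in range(1, params.n_families + 1):
        fam_records, truth = simulate_family(params, rng, fam_idx)
        records.extend(fam_records)
        truths.append(truth)
        tips: list[TipState] = truth._tips  # type: ignore[attr-defined]

        # similarity hits: symmetric noise per unordered pair, self hits at scale
        scores: dict[tuple[str, str], float] = {}
        for i, x in enumerate(tips):
            scores[(x.spec.gene_id, x.spec.gene_id)] = params.similarity_scale
            for y in tips[i + 1:]:
                # similarity tracks substitution-weighted divergence
                dist = _pair_distance(x, y) * truth._f_sub  # type: ignore[attr-defined]
                eps = params.similarity_noise * (2.0 * rng.random() - 1.0)
                val = params.similarity_scale * math.exp(-params.similarity_decay * dist) * (1.0 + eps)
                if (x.spec.role == "outparalog") != (y.spec.role == "outparalog"):
                    # deterministic tie-break: a copy exactly equidistant with the
                    # seed pair (root polytomy) must still fall outside the cluster
                    val *= 1.0 - 1e-6
                scores[(x.spec.gene_id, y.spec.gene_id)] = val
                scores[(y.spec.gene_id, x.spec.gene_id)] = val
        species_of = {t.spec.gene_id: t.spec.species for t in tips}
        for (gx, gy), val in sorted(scores.items()):
            hits.append(SimilarityHit(
                query_id=gx, subject_id=gy,
                query_species=species_of[gx], subject_species=species_of[gy],
                score=val,
            ))

        # truth cluster: main-lineage tips, seeds = the retained copies
        main = [t for t in tips if t.spec.role != "outparalog"]
        seeds = {t.spec.species: t.spec.gene_id for t in main if t.spec.role == "seed"}
        sp_a, sp_b = params.species
        seed_a, seed_b = seeds[sp_a], seeds[sp_b]
        s_score = scores[(seed_a, seed_b)]
        members = []
        for t in sorted(main, key=lambda t: (t.spec.species != sp_a, t.spec.gene_id)):
            gid = t.spec.gene_id
            if t.spec.role == "seed":
                members.append(ClusterMember(gid, t.spec.species, 1.0, is_seed=True))
            else:
                seed_gene = seeds[t.spec.species]
                denom = scores[(seed_gene, seed_gene)] - s_score
                conf = (scores[(gid, seed_gene)] - s_score) / denom if denom > 0 else 0.0
                members.append(ClusterMember(gid, t.spec.species, max(0.0, min(1.0, conf))))
        lo, hi = params.bootstrap_low if truth.confusable else params.bootstrap_high
        boots = rng.uniform(lo, hi, size=2)
        clusters.append(OrthologCluster(
            cluster_id=truth.family_id, species_a=sp_a, species_b=sp_b,
            seed_a=seed_a, seed_b=seed_b, score_s=s_score, members=members,
            seed_bootstrap_a=float(round(boots[0], 1)),
            seed_bootstrap_b=float(round(boots[1], 1)),
        ))

        # true alignment: indel-free, shorter spliceforms padded at the end
        width = params.protein_length
        alignments[truth.family_id] = {
            rec.key: rec.sequence + "-" * (width - rec.length)
            for rec in fam_records
        }

    go_annotations, pfam_domains, clan_map = _simulate_family_annotations(params, truths, rng)
    return SyntheticDataset(
        params=params, records=records, truths=truths, hits=hits,
        clusters=clusters, alignments=alignments,
        go_annotations=go_annotations, pfam_domains=pfam_domains,
        clan_map=clan_map, planted_term=params.planted_term,
    )


def _simulate_family_annotations(
    params: SimParams, truths: Sequence[FamilyTruth], rng: np.random.Generator,
) -> tuple[list[tuple[str, str]], list[tuple[str, int, str, bool]], dict[str, str]]:
    """GO/Pfam annotations for focal-species genes, planted term tied to truth."""
    focal = params.species[0]
    term_pool = [f"GO:{i:07d}" for i in range(1, params.n_go_terms + 1)]
    domain_pool = [f"PF{i:05d}" for i in range(1, params.n_pfam_domains + 1)]
    repeat_domains = set(domain_pool[: max(1, params.n_pfam_domains // 5)])
    clan_map = {
        dom: f"CL{(i % params.n_pfam_clans) + 1:04d}"
        for i, dom in enumerate(domain_pool[: 2 * params.n_pfam_domains // 3])
    }
    lo, hi = params.go_terms_per_gene
    go: list[tuple[str, str]] = []
    pfam: list[tuple[str, int, str, bool]] = []
    for truth in truths:
        for gene in sorted(truth.genes):
            if truth.genes[gene] != focal:
                continue
            n_terms = int(rng.integers(lo, hi + 1))
            for i in sorted(rng.choice(len(term_pool), size=n_terms, replace=False)):
                go.append((gene, term_pool[i]))
            p_plant = (params.planted_fg_freq if truth.consistent is False
                       else params.planted_bg_freq)
            if rng.random() < p_plant:
                go.append((gene, params.planted_term))
            n_dom = int(rng.integers(1, 5))
            order = 0
            for _ in range(n_dom):
                dom = domain_pool[int(rng.integers(0, len(domain_pool)))]
                run = int(rng.integers(1, 4)) if dom in repeat_domains else 1
                for _ in range(run):
                    pfam.append((gene, order, dom, dom in repeat_domains))
                    order += 1
    return go, pfam, clan_map


def simulate_annotations(
    rng: np.random.Generator,
    n_genes: int = 1000,
    fg_size: int = 200,
    n_background_terms: int = 50,
    planted_term: str = "GO:7777777",
    planted_fg_freq: float = 0.25,
    planted_bg_freq: float = 0.05,
) -> tuple[list[tuple[str, str]], frozenset[str], frozenset[str]]:
    """A flat annotated universe with one term planted in the foreground.

    Returns ``(gene-term pairs, foreground genes, universe)``; the planted
    term appears in the foreground at ``planted_fg_freq`` and in the rest of
    the universe at ``planted_bg_freq`` (5x lower by default).
    """
    genes = [f"g{i:05d}" for i in range(n_genes)]
    fg = frozenset(genes[:fg_size])
    pairs: list[tuple[str, str]] = []
    terms = [f"GO:{i:07d}" for i in range(1, n_background_terms + 1)]
    freqs = rng.uniform(0.02, 0.2, size=n_background_terms)
    for gene in genes:
        for term, freq in zip(terms, freqs):
            if rng.random() < freq:
                pairs.append((gene, term))
        p = planted_fg_freq if gene in fg else planted_bg_freq
        if rng.random() < p:
            pairs.append((gene, planted_term))
    return pairs, fg, frozenset(genes)


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def emit_dataset(params: SimParams, out_dir: str, seed: int) -> SyntheticDataset:
    """Write every pipeline input format to ``out_dir``; deterministic given seed."""
    from . import io as ipc_io

    ds = simulate_dataset(params, seed)
    os.makedirs(out_dir, exist_ok=True)
    aln_dir = os.path.join(out_dir, "alignments")
    os.makedirs(aln_dir, exist_ok=True)

    with open(os.path.join(out_dir, "proteins.fasta"), "w") as fh:
        fh.write(marked_fasta_text(ds.records))
    ipc_io.write_similarity_tsv(ds.hits, os.path.join(out_dir, "similarity.tsv"))
    ipc_io.write_cluster_tsv(ds.clusters, os.path.join(out_dir, "clusters.tsv"))
    for cid in sorted(ds.alignments):
        with open(os.path.join(aln_dir, f"{cid}.fasta"), "w") as fh:
            for key in sorted(ds.alignments[cid]):
                fh.write(f">{key}\n{ds.alignments[cid][key]}\n")
    ipc_io.write_annotation_tsv(ds.go_annotations, os.path.join(out_dir, "go_annotations.tsv"))
    ipc_io.write_domain_tsv(ds.pfam_domains, os.path.join(out_dir, "pfam_domains.tsv"))
    ipc_io.write_clan_map_tsv(ds.clan_map, os.path.join(out_dir, "clan_map.tsv"))
    truth_doc = [
        {
            "family_id": t.family_id,
            "genes": t.genes,
            "roles": t.roles,
            "relations": sorted(
                [sorted(pair), rel] for pair, rel in
                ((tuple(p), r) for p, r in t.relations.items())
            ),
            "confusable": t.confusable,
            "mitochondrial": t.mitochondrial,
            "consistent": t.consistent,
        }
        for t in ds.truths
    ]
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(truth_doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return ds
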