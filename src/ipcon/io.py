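"""Tabular input/output: similarity tables, cluster tables, annotations, scores.

All tables are TSV with a header row; floats are written with ``%.6g`` so
outputs are byte-stable across runs.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .ipc_core import ClusterSummary, PairScore, PAIR_TYPES
from .ortholog_clusters import ClusterError, ClusterMember, OrthologCluster, SimilarityHit

FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------------------
# Similarity tables
# ---------------------------------------------------------------------------

def read_similarity_tsv(path: str) -> list[SimilarityHit]:
    df = pd.read_csv(path, sep="\t")
    required = {"query", "subject", "qspecies", "sspecies", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing similarity columns {sorted(missing)}")
    hits = []
    for row in df.itertuples(index=False):
        hits.append(SimilarityHit(
            query_id=str(row.query), subject_id=str(row.subject),
            query_species=str(row.qspecies), subject_species=str(row.sspecies),
            score=float(row.score),
            query_coverage=float(getattr(row, "qcov", 1.0)),
            max_segment_coverage=float(getattr(row, "segcov", 1.0)),
        ))
    return hits


def write_similarity_tsv(hits: Iterable[SimilarityHit], path: str) -> None:
    df = pd.DataFrame(
        [(h.query_id, h.subject_id, h.query_species, h.subject_species,
          h.score, h.query_coverage, h.max_segment_coverage) for h in hits],
        columns=["query", "subject", "qspecies", "sspecies", "score", "qcov", "segcov"],
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# Cluster tables (InParanoid-like)
# ---------------------------------------------------------------------------

def write_cluster_tsv(clusters: Iterable[OrthologCluster], path: str) -> None:
    rows = []
    for c in clusters:
        boot = {c.seed_a: c.seed_bootstrap_a, c.seed_b: c.seed_bootstrap_b}
        for m in c.members:
            rows.append((
                c.cluster_id, m.species, m.gene_id, int(m.is_seed),
                m.confidence, boot.get(m.gene_id, None) if m.is_seed else None,
                c.score_s,
            ))
    df = pd.DataFrame(rows, columns=[
        "cluster_id", "species", "member_id", "is_seed", "confidence", "bootstrap", "S",
    ])
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_cluster_tsv(path: str) -> list[OrthologCluster]:
    """Reconstruct clusters from a table; validates disjoint membership."""
    df = pd.read_csv(path, sep="\t")
    required = {"cluster_id", "species", "member_id", "confidence", "S"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing cluster columns {sorted(missing)}")
    seen: dict[str, str] = {}
    clusters: list[OrthologCluster] = []
    for cid, group in df.groupby("cluster_id", sort=True):
        cid = str(cid)
        members: list[ClusterMember] = []
        species_order: list[str] = []
        seeds: dict[str, tuple[str, float | None]] = {}
        for row in group.itertuples(index=False):
            gene = str(row.member_id)
            if gene in seen:
                raise ClusterError(
                    f"{path}: gene {gene} appears in clusters {seen[gene]} and {cid}"
                )
            seen[gene] = cid
            sp = str(row.species)
            if sp not in species_order:
                species_order.append(sp)
            is_seed = bool(getattr(row, "is_seed", 0))
            members.append(ClusterMember(gene, sp, float(row.confidence), is_seed=is_seed))
            if is_seed:
                boot = getattr(row, "bootstrap", None)
                boot = None if boot is None or pd.isna(boot) else float(boot)
                seeds[sp] = (gene, boot)
        if len(species_order) != 2:
            raise ClusterError(f"{path}: cluster {cid} does not span exactly two species")
        sp_a, sp_b = species_order
        for sp in species_order:
            if sp not in seeds:
                # no explicit seed flags: highest-confidence member per species
                cands = [m for m in members if m.species == sp]
                best = min(cands, key=lambda m: (-m.confidence, m.gene_id))
                best.is_seed = True
                seeds[sp] = (best.gene_id, None)
        for m in members:
            if m.is_seed and abs(m.confidence - 1.0) > 1e-9:
                raise ClusterError(f"{path}: seed {m.gene_id} has confidence {m.confidence} != 1")
        clusters.append(OrthologCluster(
            cluster_id=cid, species_a=sp_a, species_b=sp_b,
            seed_a=seeds[sp_a][0], seed_b=seeds[sp_b][0],
            score_s=float(group["S"].iloc[0]), members=members,
            seed_bootstrap_a=seeds[sp_a][1], seed_bootstrap_b=seeds[sp_b][1],
        ))
    return clusters


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def write_annotation_tsv(pairs: Iterable[tuple[str, str]], path: str) -> None:
    pd.DataFrame(pairs, columns=["gene", "term"]).to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: str) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return [(str(r.gene), str(r.term)) for r in df.itertuples(index=False)]


def write_clan_map_tsv(clan_map: Mapping[str, str], path: str) -> None:
    rows = sorted(clan_map.items())
    pd.DataFrame(rows, columns=["domain", "clan"]).to_csv(path, sep="\t", index=False)


def read_clan_map_tsv(path: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return {str(r.domain): str(r.clan) for r in df.itertuples(index=False)}


def write_domain_tsv(rows: Iterable[tuple[str, int, str, bool]], path: str) -> None:
    pd.DataFrame(rows, columns=["gene", "order", "domain", "repeat_type"]).to_csv(
        path, sep="\t", index=False
    )


def read_domain_tsv(path: str) -> list[tuple[str, int, str, bool]]:
    df = pd.read_csv(path, sep="\t")
    return [
        (str(r.gene), int(r.order), str(r.domain), bool(r.repeat_type))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Alignments (FASTA, gapped)
# ---------------------------------------------------------------------------

def read_alignment_fasta(path: str) -> dict[str, str]:
    aln: dict[str, str] = {}
    key = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if key is not None:
                    aln[key] = "".join(chunks)
                key = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if key is not None:
        aln[key] = "".join(chunks)
    widths = {len(s) for s in aln.values()}
    if len(widths) > 1:
        raise ValueError(f"{path}: aligned sequences have unequal lengths {sorted(widths)}")
    return aln


# ---------------------------------------------------------------------------
# Scores and summaries
# ---------------------------------------------------------------------------

def write_pair_scores_tsv(rows: Iterable[PairScore], path: str) -> None:
    df = pd.DataFrame(
        [(r.cluster_id, r.pair_type, r.gene_a, r.gene_b, r.id_a, r.id_b,
          r.introns_shared, r.introns_seq_a, r.introns_seq_b,
          r.ipc if r.ipc is not None else "", r.identity) for r in rows],
        columns=["cluster_id", "pair_type", "gene_a", "gene_b", "id_a", "id_b",
                 "introns_shared", "introns_a", "introns_b", "ipc", "identity"],
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_cluster_summaries_tsv(summaries: Iterable[ClusterSummary], path: str) -> None:
    rows = []
    for s in summaries:
        row: dict = {
            "cluster_id": s.cluster_id,
            "is_multi": int(s.is_multi),
            "n_members": s.n_members,
            "seed_pair_ipc": s.seed_pair_ipc,
            "max_ortholog_pair_ipc": s.max_ortholog_pair_ipc,
            "consistent": "" if s.consistent is None else int(s.consistent),
            "min_seed_bootstrap": s.min_seed_bootstrap,
        }
        for t in PAIR_TYPES:
            row[f"mean_ipc_{t}"] = s.mean_ipc.get(t)
            row[f"mean_identity_{t}"] = s.mean_identity.get(t)
            row[f"n_pairs_{t}"] = s.n_pairs.get(t, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
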