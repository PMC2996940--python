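"""Pipeline orchestration: cluster -> extend -> align -> score -> analyze -> enrich.

``run_pipeline`` drives the file-based pipeline from a single config;
``analyze_dataset`` runs the same stages on an in-memory
:class:`~ipcon.synthetic_data.SyntheticDataset`, which is what the test-bench
and the worked examples use.  Both produce the same machine-readable report:
per-pair-type mean IPC, Mann-Whitney-Wilcoxon p-values, identity-binned log2
ratios, Spearman correlations, agreement-by-bootstrap, consistency sets and
(when annotations are provided) term enrichment with representatives.
"""

from __future__ import annotations

import json
import logging
import os
import shlex
import subprocess
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import io as ipc_io
from .comparative_stats import compare_pair_types, gene_consistency_sets
from .enrichment import (
    AnnotationMap, EnrichmentResult, build_term_network, clan_rollup,
    collapse_repeats, filter_oversize, property_tests,
)
from .gene_structures import ProteinRecord, parse_marked_fasta, select_spliceforms
from .ipc_core import ClusterScorer, ClusterSummary, IpcFormula, PairScore, pad_alignment
from .ortholog_clusters import (
    ExtendedCluster, HitIndex, OrthologCluster, build_clusters, extend_clusters,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Flat-key configuration for the file-based pipeline."""

    marked_fasta: str
    similarity_tsv: str
    out_dir: str
    clusters_tsv: str | None = None       # precomputed (InParanoid-like); else BBH clustering
    alignments_dir: str | None = None     # per-cluster FASTA named <cluster_id>.fasta
    aligner_template: str | None = None   # e.g. "mafft --auto {infile}" (stdout = FASTA)
    go_annotations_tsv: str | None = None
    pfam_domains_tsv: str | None = None
    clan_map_tsv: str | None = None
    ipc_formula: IpcFormula = "fraction"
    bins: int = 10
    bootstrap_threshold: float = 90.0
    fdr: float = 0.01
    max_cluster_size: int = 200
    mww_mode: str = "cluster_means"
    overlap_cutoff: float = 0.5
    segment_cutoff: float = 0.25
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


# ---------------------------------------------------------------------------
# Core analysis shared by the file-based and in-memory entry points
# ---------------------------------------------------------------------------

@dataclass
class AnalysisResult:
    report: dict
    summaries: list[ClusterSummary]
    pair_rows: list[PairScore]
    extended: list[ExtendedCluster]
    consistency_sets: tuple[set[str], set[str], set[str]]
    go_results: list[EnrichmentResult] = field(default_factory=list)
    go_representatives: list[tuple[str, frozenset[str]]] = field(default_factory=list)
    pfam_results: list[EnrichmentResult] = field(default_factory=list)
    pfam_representatives: list[tuple[str, frozenset[str]]] = field(default_factory=list)


def _stage(name: str):
    logger.info("stage: %s", name)


def run_analysis(
    records: Sequence[ProteinRecord],
    hits,
    clusters: Sequence[OrthologCluster] | None,
    alignments: Mapping[str, Mapping[str, str]] | None,
    *,
    go_annotations: Sequence[tuple[str, str]] | None = None,
    pfam_domains: Sequence[tuple[str, int, str, bool]] | None = None,
    clan_map: Mapping[str, str] | None = None,
    ipc_formula: IpcFormula = "fraction",
    bins: int = 10,
    bootstrap_threshold: float = 90.0,
    fdr: float = 0.01,
    max_cluster_size: int = 200,
    mww_mode: str = "cluster_means",
    overlap_cutoff: float = 0.5,
    segment_cutoff: float = 0.25,
    aligner=None,
) -> AnalysisResult:
    """Run clustering (if needed), extension, scoring and all statistics.

    ``alignments`` maps cluster_id -> {record key -> gapped sequence}; a
    missing cluster falls back to ``aligner(records) -> mapping`` or, as a
    last resort, gap-padding (valid only for indel-free inputs).
    """
    _stage("spliceforms")
    kept, pool = select_spliceforms(records)
    pool_ids: dict[str, list[str]] = {}
    for rec in pool:
        pool_ids.setdefault(rec.gene_id, []).append(rec.spliceform_id)
    records_by_gene: dict[tuple[str, str], list[ProteinRecord]] = {}
    for rec in list(kept) + list(pool):
        records_by_gene.setdefault((rec.species, rec.gene_id), []).append(rec)
    organelle = {rec.gene_id: rec.organelle for rec in kept}

    _stage("clustering")
    index = hits if isinstance(hits, HitIndex) else HitIndex(hits, overlap_cutoff, segment_cutoff)
    if clusters is None:
        clusters = build_clusters(index)
    _stage("extension")
    extended = extend_clusters(clusters, index, organelle=organelle, spliceform_pool=pool_ids)
    n_mito_excluded = len(clusters) - len(extended)

    _stage("scoring")
    scorer = ClusterScorer(records_by_gene, formula=ipc_formula)
    summaries: list[ClusterSummary] = []
    pair_rows: list[PairScore] = []
    for ext in extended:
        aln = dict(alignments.get(ext.cluster_id, {})) if alignments else {}
        if not aln:
            needed = _needed_records(ext, records_by_gene)
            if aligner is not None:
                aln = aligner(needed)
            else:
                aln = pad_alignment(needed)
        summary, rows = scorer.score_extended_cluster(ext, aln)
        summaries.append(summary)
        pair_rows.extend(rows)

    _stage("analysis")
    report = compare_pair_types(
        summaries, pair_rows, bins=bins,
        bootstrap_threshold=bootstrap_threshold, mww_mode=mww_mode,
    )
    report["n_clusters_mitochondrial_excluded"] = n_mito_excluded
    report["cno_cni_availability"] = _availability(extended)

    # consistency sets on the focal (first) species, oversize clusters removed
    focal = extended[0].cluster.species_a if extended else None
    label = (f"{extended[0].cluster.species_a}-{extended[0].cluster.species_b}"
             if extended else "comparison")
    sizes = {e.cluster_id: len(e.cluster.members) for e in extended if e.cluster.is_multi}
    kept_ids, removed_ids = filter_oversize(sizes, max_genes=max_cluster_size)
    membership = {
        e.cluster_id: sorted(
            m.gene_id for m in e.cluster.members if m.species == focal
        )
        for e in extended if e.cluster_id in set(kept_ids)
    }
    usable = [s for s in summaries if s.cluster_id in membership]
    only_cons, only_incons, both = gene_consistency_sets(
        {label: usable}, {label: membership}
    )
    report["consistency_sets"] = {
        "focal_species": focal,
        "n_only_consistent": len(only_cons),
        "n_only_inconsistent": len(only_incons),
        "n_ambiguous": len(both),
        "n_oversize_clusters_removed": len(removed_ids),
        "oversize_clusters": removed_ids,
    }

    result = AnalysisResult(
        report=report, summaries=summaries, pair_rows=pair_rows,
        extended=extended, consistency_sets=(only_cons, only_incons, both),
    )

    _stage("enrichment")
    universe = only_cons | only_incons
    fg = only_incons
    if go_annotations is not None and fg and universe - fg:
        ann = AnnotationMap.from_pairs(
            [(g, t) for g, t in go_annotations if g in universe], universe=universe
        )
        if ann.terms():
            result.go_results, network = build_term_network(fg, ann, fdr=fdr)
            result.go_representatives = network.representatives
            report["go_enrichment"] = _enrichment_section(result.go_results,
                                                          result.go_representatives)
    if pfam_domains is not None and fg and universe - fg:
        domain_sets = _pfam_annotation_pairs(pfam_domains, universe)
        if clan_map:
            pairs = [(g, clan_map.get(d, d)) for g, d in domain_sets]
        else:
            pairs = domain_sets
        ann = AnnotationMap.from_pairs(pairs, universe=universe)
        if ann.terms():
            result.pfam_results, network = build_term_network(fg, ann, fdr=fdr)
            result.pfam_representatives = network.representatives
            report["pfam_enrichment"] = _enrichment_section(result.pfam_results,
                                                            result.pfam_representatives)
    if pfam_domains is not None and fg and universe - fg:
        report["property_tests"] = _property_section(
            fg, universe - fg, records_by_gene, pfam_domains
        )
    return result


def _needed_records(ext, records_by_gene) -> list[ProteinRecord]:
    genes = set(ext.cluster.member_ids)
    genes.update(g for g in ext.cno.values() if g)
    genes.update(g for g in ext.cni.values() if g)
    out: list[ProteinRecord] = []
    for (sp, gene), recs in records_by_gene.items():
        if gene in genes:
            out.extend(recs)
    return sorted(out, key=lambda r: r.key)


def _availability(extended: Sequence[ExtendedCluster]) -> dict:
    both = either = none = total = 0
    for ext in extended:
        for gene in ext.cluster.member_ids:
            total += 1
            has_cno = ext.cno.get(gene) is not None
            has_cni = ext.cni.get(gene) is not None
            if has_cno and has_cni:
                both += 1
            elif has_cno or has_cni:
                either += 1
            else:
                none += 1
    return {
        "n_members": total,
        "fraction_both": both / total if total else None,
        "fraction_either": either / total if total else None,
        "fraction_neither": none / total if total else None,
    }


def _pfam_annotation_pairs(
    pfam_domains: Sequence[tuple[str, int, str, bool]], universe: set[str]
) -> list[tuple[str, str]]:
    by_gene: dict[str, list[tuple[int, str, bool]]] = {}
    for gene, order, domain, repeat in pfam_domains:
        if gene in universe:
            by_gene.setdefault(gene, []).append((order, domain, repeat))
    pairs: list[tuple[str, str]] = []
    for gene in sorted(by_gene):
        hits = sorted(by_gene[gene])
        repeat_doms = {d for _, d, rep in hits if rep}
        pseudo, _ = collapse_repeats([d for _, d, _ in hits], repeat_doms)
        pairs.extend((gene, dom) for dom in sorted(set(pseudo)))
    return pairs


def _property_section(fg, bg, records_by_gene, pfam_domains) -> dict:
    lengths: dict[str, int] = {}
    introns: dict[str, int] = {}
    for (sp, gene), recs in records_by_gene.items():
        primary = min(recs, key=lambda r: (-r.length, r.spliceform_id))
        lengths[gene] = primary.length
        introns[gene] = primary.n_introns
    by_gene: dict[str, list[tuple[int, str, bool]]] = {}
    for gene, order, domain, repeat in pfam_domains:
        by_gene.setdefault(gene, []).append((order, domain, repeat))
    pseudo_counts: dict[str, int] = {}
    for gene, hits in by_gene.items():
        hits = sorted(hits)
        repeat_doms = {d for _, d, rep in hits if rep}
        _, count = collapse_repeats([d for _, d, _ in hits], repeat_doms)
        pseudo_counts[gene] = count

    def vectors(genes: set[str]) -> dict[str, list[float]]:
        genes_sorted = sorted(genes)
        return {
            "length_aa": [float(lengths[g]) for g in genes_sorted if g in lengths],
            "n_introns": [float(introns[g]) for g in genes_sorted if g in introns],
            "n_pseudo_domains": [float(pseudo_counts.get(g, 0)) for g in genes_sorted],
        }

    return property_tests(vectors(set(fg)), vectors(set(bg)))


def _enrichment_section(results: Sequence[EnrichmentResult],
                        representatives) -> dict:
    sig = [r for r in results if r.significant]
    return {
        "n_terms_tested": len(results),
        "n_significant": len(sig),
        "significant_terms": [
            {"term": r.term, "direction": r.direction, "p_two_sided": r.p_two_sided,
             "fg_count": r.fg_count, "bg_count": r.bg_count}
            for r in sorted(sig, key=lambda r: (r.p_two_sided, r.term))
        ],
        "representatives": [
            {"term": term, "n_absorbed": len(group), "absorbed": sorted(group)}
            for term, group in representatives
        ],
    }


# ---------------------------------------------------------------------------
# In-memory entry point for simulated datasets
# ---------------------------------------------------------------------------

def analyze_dataset(
    dataset,
    *,
    cluster_source: str = "table",
    with_annotations: bool = True,
    **kwargs,
) -> AnalysisResult:
    """Run the full analysis on a :class:`SyntheticDataset`.

    ``cluster_source`` is ``"table"`` (consume the emitted InParanoid-like
    clusters, with bootstraps) or ``"similarity"`` (recluster from the hit
    table by bidirectional best hits).
    """
    clusters = dataset.clusters if cluster_source == "table" else None
    alignments = dataset.alignments if cluster_source == "table" else None
    return run_analysis(
        dataset.records, dataset.hits, clusters, alignments,
        go_annotations=dataset.go_annotations if with_annotations else None,
        pfam_domains=dataset.pfam_domains if with_annotations else None,
        clan_map=dataset.clan_map if with_annotations else None,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# File-based pipeline
# ---------------------------------------------------------------------------

def _external_aligner(template: str):
    def align(records: Sequence[ProteinRecord]) -> dict[str, str]:
        import tempfile

        from .gene_structures import marked_fasta_text

        with tempfile.NamedTemporaryFile("w", suffix=".fasta", delete=False) as fh:
            fh.write(marked_fasta_text(records))
            infile = fh.name
        try:
            cmd = shlex.split(template.format(infile=infile))
            proc = subprocess.run(cmd, capture_output=True, text=True, check=True)
            aln: dict[str, str] = {}
            key = None
            chunks: list[str] = []
            for line in proc.stdout.splitlines():
                line = line.strip()
                if line.startswith(">"):
                    if key is not None:
                        aln[key] = "".join(chunks).upper()
                    key = line[1:].split()[0]
                    chunks = []
                elif line:
                    chunks.append(line)
            if key is not None:
                aln[key] = "".join(chunks).upper()
            return aln
        finally:
            os.unlink(infile)

    return align


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages from files and write TSV outputs plus report.json."""
    for stage, path in (("input", config.marked_fasta), ("input", config.similarity_tsv)):
        if not os.path.exists(path):
            raise PipelineError(f"{stage} stage: missing file {path}")
    os.makedirs(config.out_dir, exist_ok=True)

    with open(config.marked_fasta) as fh:
        records = parse_marked_fasta(fh.read())
    hits = ipc_io.read_similarity_tsv(config.similarity_tsv)
    clusters = None
    if config.clusters_tsv:
        if not os.path.exists(config.clusters_tsv):
            raise PipelineError(f"cluster stage: missing file {config.clusters_tsv}")
        clusters = ipc_io.read_cluster_tsv(config.clusters_tsv)

    alignments: dict[str, dict[str, str]] = {}
    if config.alignments_dir:
        if not os.path.isdir(config.alignments_dir):
            raise PipelineError(f"align stage: missing directory {config.alignments_dir}")
        for name in sorted(os.listdir(config.alignments_dir)):
            if name.endswith((".fasta", ".fa")):
                cid = name.rsplit(".", 1)[0]
                alignments[cid] = ipc_io.read_alignment_fasta(
                    os.path.join(config.alignments_dir, name)
                )

    go = ipc_io.read_annotation_tsv(config.go_annotations_tsv) if config.go_annotations_tsv else None
    pfam = ipc_io.read_domain_tsv(config.pfam_domains_tsv) if config.pfam_domains_tsv else None
    clans = ipc_io.read_clan_map_tsv(config.clan_map_tsv) if config.clan_map_tsv else None

    result = run_analysis(
        records, hits, clusters, alignments,
        go_annotations=go, pfam_domains=pfam, clan_map=clans,
        ipc_formula=config.ipc_formula, bins=config.bins,
        bootstrap_threshold=config.bootstrap_threshold, fdr=config.fdr,
        max_cluster_size=config.max_cluster_size, mww_mode=config.mww_mode,
        overlap_cutoff=config.overlap_cutoff, segment_cutoff=config.segment_cutoff,
        aligner=_external_aligner(config.aligner_template) if config.aligner_template else None,
    )

    ipc_io.write_pair_scores_tsv(result.pair_rows, os.path.join(config.out_dir, "pair_scores.tsv"))
    ipc_io.write_cluster_summaries_tsv(
        result.summaries, os.path.join(config.out_dir, "cluster_summaries.tsv")
    )
    if result.go_results:
        _write_enrichment_tsv(result.go_results, os.path.join(config.out_dir, "enrichment_go.tsv"))
    if result.pfam_results:
        _write_enrichment_tsv(result.pfam_results, os.path.join(config.out_dir, "enrichment_pfam.tsv"))
    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")
    return result.report


def _write_enrichment_tsv(results: Sequence[EnrichmentResult], path: str) -> None:
    df = pd.DataFrame(
        [(r.term, r.fg_count, r.bg_count, r.fg_size, r.bg_size,
          r.p_enriched, r.p_depleted, r.p_two_sided, r.direction, int(r.significant))
         for r in sorted(results, key=lambda r: (r.p_two_sided, r.term))],
        columns=["term", "fg_count", "bg_count", "fg_size", "bg_size",
                 "p_enriched", "p_depleted", "p_two_sided", "direction", "significant"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
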