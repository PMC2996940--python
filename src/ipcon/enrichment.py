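"""Hypergeometric term enrichment with FDR control and term networks.

The foreground (genes found only in inconsistent multi-clusters) is tested
term by term against a background universe (foreground plus the genes found
only in consistent multi-clusters) under the hypergeometric null; both
enrichment and depletion tails are computed, the two-sided p-value (doubled
minimal tail, capped at 1) feeds Benjamini-Hochberg FDR control at 1%.

Term interdependence is handled empirically: term B is associated with term A
when B loses significance once all A-annotated genes are excluded; the
associations form a network from which maximally connected representatives
are greedily selected.  Pfam domains can be rolled up to clans, and runs of
identical Repeat/Motif-type domains collapse to one pseudo-domain before
counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import fmean
from typing import Iterable, Mapping, Sequence

import networkx as nx
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .comparative_stats import mww_test

logger = logging.getLogger(__name__)

DEFAULT_FDR = 0.01
DEFAULT_MAX_CLUSTER_GENES = 200


class EnrichmentError(ValueError):
    pass


@dataclass
class AnnotationMap:
    """gene -> set of terms, with an explicit background universe."""

    gene_terms: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        stray = set(self.gene_terms) - set(self.universe)
        if stray:
            raise EnrichmentError(
                f"{len(stray)} annotated genes outside the universe, e.g. {sorted(stray)[:3]}"
            )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]],
                   universe: Iterable[str] | None = None) -> "AnnotationMap":
        acc: dict[str, set[str]] = {}
        for gene, term in pairs:
            acc.setdefault(gene, set()).add(term)
        uni = frozenset(universe) if universe is not None else frozenset(acc)
        return cls({g: frozenset(t) for g, t in acc.items() if g in uni}, uni)

    def genes_with(self, term: str) -> frozenset[str]:
        return frozenset(g for g, ts in self.gene_terms.items() if term in ts)

    def terms(self) -> list[str]:
        seen: set[str] = set()
        for ts in self.gene_terms.values():
            seen.update(ts)
        return sorted(seen)

    def restricted(self, universe: Iterable[str]) -> "AnnotationMap":
        uni = frozenset(universe)
        return AnnotationMap(
            {g: ts for g, ts in self.gene_terms.items() if g in uni}, uni
        )


@dataclass
class EnrichmentResult:
    term: str
    fg_count: int
    bg_count: int
    fg_size: int
    bg_size: int
    p_enriched: float
    p_depleted: float
    direction: str  # "enriched" | "depleted"
    p_two_sided: float
    significant: bool = False


# ---------------------------------------------------------------------------
# Oversize-cluster filtering
# ---------------------------------------------------------------------------

def filter_oversize(
    cluster_sizes: Mapping[str, int],
    max_genes: int = DEFAULT_MAX_CLUSTER_GENES,
) -> tuple[list[str], list[str]]:
    """Split multi-cluster ids into (kept, removed) by total gene count (strict >)."""
    kept, removed = [], []
    for cid in sorted(cluster_sizes):
        if cluster_sizes[cid] > max_genes:
            removed.append(cid)
            logger.info("cluster %s removed: %d genes > %d", cid, cluster_sizes[cid], max_genes)
        else:
            kept.append(cid)
    return kept, removed


# ---------------------------------------------------------------------------
# Hypergeometric test + FDR
# ---------------------------------------------------------------------------

def hypergeom_term_test(
    term: str, fg: frozenset[str] | set[str], annotations: AnnotationMap
) -> EnrichmentResult:
    """Hypergeometric enrichment/depletion tails for one term.

    With universe size N, K genes carrying the term, a foreground of size n
    and k foreground genes carrying the term: p_enriched = P(X >= k),
    p_depleted = P(X <= k) for X ~ Hypergeom(N, K, n).
    """
    fg = set(fg)
    if not fg <= set(annotations.universe):
        raise EnrichmentError("foreground is not a subset of the universe")
    carriers = annotations.genes_with(term)
    if not carriers:
        raise EnrichmentError(f"term {term!r} absent from the universe")
    big_n = len(annotations.universe)
    big_k = len(carriers)
    n = len(fg)
    k = len(carriers & fg)
    dist = stats.hypergeom(big_n, big_k, n)
    p_enr = float(dist.sf(k - 1))
    p_dep = float(dist.cdf(k))
    direction = "enriched" if p_enr <= p_dep else "depleted"
    p_two = min(1.0, 2.0 * min(p_enr, p_dep))
    return EnrichmentResult(
        term=term, fg_count=k, bg_count=big_k, fg_size=n, bg_size=big_n,
        p_enriched=p_enr, p_depleted=p_dep, direction=direction, p_two_sided=p_two,
    )


def bh_significant(
    results: Sequence[EnrichmentResult], fdr: float = DEFAULT_FDR
) -> list[EnrichmentResult]:
    """Benjamini-Hochberg step-up on the two-sided p-values; flags in place."""
    if not results:
        return []
    pvals = [r.p_two_sided for r in results]
    reject, _, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    for r, flag in zip(results, reject):
        r.significant = bool(flag)
    return list(results)


def run_term_tests(
    fg: Iterable[str], annotations: AnnotationMap, fdr: float = DEFAULT_FDR
) -> list[EnrichmentResult]:
    """Run the hypergeometric test for every annotated term, then BH."""
    fg = frozenset(fg)
    results = [hypergeom_term_test(t, fg, annotations) for t in annotations.terms()]
    return bh_significant(results, fdr)


# ---------------------------------------------------------------------------
# Term association network and representatives
# ---------------------------------------------------------------------------

@dataclass
class TermNetwork:
    graph: nx.Graph
    representatives: list[tuple[str, frozenset[str]]] = field(default_factory=list)


def term_association_edges(
    fg: Iterable[str], annotations: AnnotationMap, fdr: float = DEFAULT_FDR,
    significant_terms: Sequence[str] | None = None,
) -> nx.Graph:
    """Edges (A, B): B significant on the full set, not after excluding A's genes.

    For each significant term A, the entire test + FDR procedure is re-run on
    the universe minus the A-annotated genes; associations are directed A->B
    but stored in an undirected graph for link counting.
    """
    fg = frozenset(fg)
    if significant_terms is None:
        significant_terms = [
            r.term for r in run_term_tests(fg, annotations, fdr) if r.significant
        ]
    graph = nx.Graph()
    graph.add_nodes_from(significant_terms)
    sig_set = set(significant_terms)
    for term_a in significant_terms:
        drop = annotations.genes_with(term_a)
        reduced_universe = set(annotations.universe) - set(drop)
        if not reduced_universe:
            continue
        reduced = annotations.restricted(reduced_universe)
        reduced_fg = fg & reduced_universe
        still = {
            r.term for r in run_term_tests(reduced_fg, reduced, fdr) if r.significant
        }
        for term_b in sig_set - {term_a}:
            if term_b not in still:
                graph.add_edge(term_a, term_b)
    return graph


def pick_representatives(graph: nx.Graph) -> list[tuple[str, frozenset[str]]]:
    """Greedy selection: repeatedly take the most-linked node (ties: smallest id),
    absorb its current neighbors, delete them, repeat.  Isolated nodes become
    their own representatives."""
    work = graph.copy()
    reps: list[tuple[str, frozenset[str]]] = []
    while work.number_of_nodes():
        node = min(work.nodes, key=lambda n: (-work.degree(n), n))
        neighbors = frozenset(work.neighbors(node))
        reps.append((node, neighbors))
        work.remove_nodes_from({node} | neighbors)
    return reps


def build_term_network(
    fg: Iterable[str], annotations: AnnotationMap, fdr: float = DEFAULT_FDR
) -> tuple[list[EnrichmentResult], TermNetwork]:
    results = run_term_tests(fg, annotations, fdr)
    significant = [r.term for r in results if r.significant]
    graph = term_association_edges(fg, annotations, fdr, significant_terms=significant)
    network = TermNetwork(graph=graph, representatives=pick_representatives(graph))
    return results, network


# ---------------------------------------------------------------------------
# Pfam helpers
# ---------------------------------------------------------------------------

def clan_rollup(
    annotations: AnnotationMap, clan_map: Mapping[str, str]
) -> AnnotationMap:
    """Replace each domain by its clan where mapped; deduplicate per gene."""
    rolled = {
        gene: frozenset(clan_map.get(d, d) for d in doms)
        for gene, doms in annotations.gene_terms.items()
    }
    return AnnotationMap(rolled, annotations.universe)


def collapse_repeats(
    domain_hits: Sequence[str], repeat_type: Mapping[str, bool] | set[str]
) -> tuple[list[str], int]:
    """Collapse maximal consecutive runs of the same Repeat/Motif-type domain.

    ``domain_hits`` is ordered along the protein.  Returns the pseudo-domain
    list and its length.
    """
    is_repeat = (
        repeat_type.__contains__ if isinstance(repeat_type, (set, frozenset))
        else lambda d: bool(repeat_type.get(d, False))
    )
    out: list[str] = []
    for dom in domain_hits:
        if out and out[-1] == dom and is_repeat(dom):
            continue
        out.append(dom)
    return out, len(out)


# ---------------------------------------------------------------------------
# Protein property comparison
# ---------------------------------------------------------------------------

def property_tests(
    fg_values: Mapping[str, Sequence[float]],
    bg_values: Mapping[str, Sequence[float]],
) -> dict[str, dict[str, float | None]]:
    """Two-sided MWW and percent mean difference per property.

    ``fg_values``/``bg_values`` map property names (e.g. length_aa,
    n_pseudo_domains, n_introns) to per-gene vectors.  The difference is
    ``100 * (mean_fg / mean_bg - 1)``.
    """
    out: dict[str, dict[str, float | None]] = {}
    for prop in sorted(set(fg_values) & set(bg_values)):
        fg = list(fg_values[prop])
        bg = list(bg_values[prop])
        if not fg or not bg:
            out[prop] = {"p": None, "percent_difference": None}
            continue
        mean_bg = fmean(bg)
        diff = None if mean_bg == 0 else 100.0 * (fmean(fg) / mean_bg - 1.0)
        out[prop] = {"p": mww_test(fg, bg), "percent_difference": diff}
    return out
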