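"""Statistical comparisons between the four pair types.

Covers the distribution tests (Mann-Whitney-Wilcoxon), identity-controlled
binning with combined equal-count boundaries and per-bin log2 IPC ratios,
Spearman correlations between IPC and sequence identity, and the
seed-agreement analysis split by seed bootstrap support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import fmean
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .ipc_core import PAIR_TYPES, ClusterSummary, PairScore


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Mann-Whitney-Wilcoxon
# ---------------------------------------------------------------------------

EXACT_LIMIT = 20  # combined sample size up to which the exact null is used


def mww_test(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Two-sided Mann-Whitney-Wilcoxon rank-sum p-value.

    Exact for combined n <= 20 (full permutation enumeration when ties are
    present), normal approximation with tie correction otherwise.
    """
    if len(xs) == 0 or len(ys) == 0:
        raise StatsError("MWW requires two non-empty samples")
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    n = len(xs) + len(ys)
    if n <= EXACT_LIMIT:
        if len(np.unique(np.concatenate([xs, ys]))) == n:
            method = "exact"
        else:
            method = stats.PermutationMethod(n_resamples=np.inf)
        return float(stats.mannwhitneyu(xs, ys, alternative="two-sided", method=method).pvalue)
    res = stats.mannwhitneyu(xs, ys, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Identity-controlled binning
# ---------------------------------------------------------------------------

@dataclass
class BinSpec:
    """Combined equal-count bin boundaries and per-bin statistics."""

    k: int
    boundaries: list[float]
    boundaries_type1: list[float]
    boundaries_type2: list[float]
    mean_ipc_type1: list[float | None] = field(default_factory=list)
    mean_ipc_type2: list[float | None] = field(default_factory=list)
    counts_type1: list[int] = field(default_factory=list)
    counts_type2: list[int] = field(default_factory=list)
    log2_ratio: list[float | None] = field(default_factory=list)


def equal_count_boundaries(values: Sequence[float], k: int) -> list[float]:
    """k-1 boundaries splitting sorted values into k equal-count bins.

    Boundary j is the midpoint between the adjacent order statistics at the
    j-th k-quantile split.
    """
    n = len(values)
    if n < k:
        raise StatsError(f"sample of size {n} cannot fill {k} bins")
    xs = np.sort(np.asarray(values, dtype=float))
    bounds = []
    for j in range(1, k):
        split = round(j * n / k)
        split = min(max(split, 1), n - 1)
        bounds.append(float((xs[split - 1] + xs[split]) / 2.0))
    return bounds


def combined_bin_boundaries(
    xs: Sequence[float], ys: Sequence[float], k: int = 10
) -> tuple[list[float], list[float], list[float]]:
    """Average the two pair types' equal-count boundaries position-wise.

    Returns ``(combined, boundaries_x, boundaries_y)``.
    """
    bx = equal_count_boundaries(xs, k)
    by = equal_count_boundaries(ys, k)
    combined = [(a + b) / 2.0 for a, b in zip(bx, by)]
    return combined, bx, by


def assign_bins(values: Sequence[float], boundaries: Sequence[float]) -> list[int]:
    """Bin index per value; intervals are half-open, right-inclusive.

    A value exactly on a boundary goes to the lower bin; bin 0 is
    ``(-inf, b0]`` and the last bin ``(b_last, +inf)``.
    """
    out = []
    for v in values:
        idx = 0
        for b in boundaries:
            if v > b:
                idx += 1
            else:
                break
        out.append(idx)
    return out


def binned_log2_ratio(
    pairs_type1: Sequence[tuple[float, float | None]],
    pairs_type2: Sequence[tuple[float, float | None]],
    boundaries: Sequence[float],
) -> BinSpec:
    """Per-bin log2(mean IPC type1 / mean IPC type2) over combined boundaries.

    Each pair is ``(identity, ipc)``; undefined IPC values are excluded from
    means.  A bin where either type is empty or has mean 0 gets ``None``
    (flagged undefined, never +-inf).
    """
    k = len(boundaries) + 1
    spec = BinSpec(k=k, boundaries=list(boundaries),
                   boundaries_type1=[], boundaries_type2=[])
    per_bin: list[tuple[list[float], list[float]]] = [([], []) for _ in range(k)]
    counts1 = [0] * k
    counts2 = [0] * k
    for (pairs, slot, counts) in ((pairs_type1, 0, counts1), (pairs_type2, 1, counts2)):
        idents = [p[0] for p in pairs]
        for idx, (identity, value) in zip(assign_bins(idents, boundaries), pairs):
            counts[idx] += 1
            if value is not None:
                per_bin[idx][slot].append(value)
    spec.counts_type1 = counts1
    spec.counts_type2 = counts2
    for vals1, vals2 in per_bin:
        m1 = fmean(vals1) if vals1 else None
        m2 = fmean(vals2) if vals2 else None
        spec.mean_ipc_type1.append(m1)
        spec.mean_ipc_type2.append(m2)
        if m1 is None or m2 is None or m1 == 0.0 or m2 == 0.0:
            spec.log2_ratio.append(None)
        else:
            spec.log2_ratio.append(math.log2(m1 / m2))
    return spec


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def spearman_ipc_identity(
    pairs: Sequence[tuple[float, float]]
) -> tuple[float | None, float | None]:
    """Spearman rho (average-rank ties) and t-approximation p for (ipc, identity).

    Returns ``(None, None)`` for constant input, flagged rather than NaN.
    """
    if len(pairs) < 3:
        raise StatsError("Spearman correlation needs at least 3 pairs")
    ipcs = np.array([p[0] for p in pairs], dtype=float)
    idents = np.array([p[1] for p in pairs], dtype=float)
    if np.all(ipcs == ipcs[0]) or np.all(idents == idents[0]):
        return None, None
    rho, p = stats.spearmanr(ipcs, idents)
    return float(rho), float(p)


def spearman_by_type(
    rows: Iterable[PairScore],
) -> dict[str, dict[str, float | None]]:
    out: dict[str, dict[str, float | None]] = {}
    for ptype in PAIR_TYPES:
        pts = [(r.ipc, r.identity) for r in rows if r.pair_type == ptype and r.ipc is not None]
        if len(pts) < 3:
            out[ptype] = {"rho": None, "p": None, "n": len(pts)}
            continue
        rho, p = spearman_ipc_identity(pts)  # type: ignore[arg-type]
        out[ptype] = {"rho": rho, "p": p, "n": len(pts)}
    return out


# ---------------------------------------------------------------------------
# Agreement with seed assignments, by bootstrap support
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    threshold: float
    fraction_high: float | None
    fraction_low: float | None
    n_high: int
    n_low: int
    n_unknown_bootstrap: int


def agreement_by_bootstrap(
    summaries: Iterable[ClusterSummary], threshold: float = 90.0
) -> AgreementReport:
    """Fraction of consistent multi-clusters, split by min seed bootstrap.

    A cluster is consistent when its seed pair attains the highest IPC among
    all its ortholog pairs (ties agree).  Clusters with unknown bootstrap or
    undetermined consistency are excluded and counted.
    """
    high = []
    low = []
    unknown = 0
    for s in summaries:
        if not s.is_multi or s.consistent is None:
            continue
        if s.min_seed_bootstrap is None:
            unknown += 1
            continue
        (high if s.min_seed_bootstrap >= threshold else low).append(s.consistent)
    return AgreementReport(
        threshold=threshold,
        fraction_high=(sum(high) / len(high)) if high else None,
        fraction_low=(sum(low) / len(low)) if low else None,
        n_high=len(high),
        n_low=len(low),
        n_unknown_bootstrap=unknown,
    )


# ---------------------------------------------------------------------------
# Gene-level consistency sets across species comparisons
# ---------------------------------------------------------------------------

def gene_consistency_sets(
    summaries_by_comparison: Mapping[str, Sequence[ClusterSummary]],
    membership_by_comparison: Mapping[str, Mapping[str, Sequence[str]]],
) -> tuple[set[str], set[str], set[str]]:
    """Split focal-species genes into only-consistent / only-inconsistent / both.

    ``membership_by_comparison[label][cluster_id]`` lists the focal-species
    genes of that cluster.  Only genes appearing in at least one multi-cluster
    with determined consistency are classified; genes seen on both sides
    across comparisons land in ``both`` (excluded from enrichment downstream).
    """
    consistent_genes: set[str] = set()
    inconsistent_genes: set[str] = set()
    for label, summaries in summaries_by_comparison.items():
        membership = membership_by_comparison.get(label, {})
        for s in summaries:
            if not s.is_multi or s.consistent is None:
                continue
            genes = membership.get(s.cluster_id, ())
            (consistent_genes if s.consistent else inconsistent_genes).update(genes)
    both = consistent_genes & inconsistent_genes
    return consistent_genes - both, inconsistent_genes - both, both


# ---------------------------------------------------------------------------
# Comparison report
# ---------------------------------------------------------------------------

def mean_ipc_by_type(
    summaries: Sequence[ClusterSummary], mode: str = "cluster_means",
    rows: Sequence[PairScore] | None = None,
) -> dict[str, list[float]]:
    """Collect per-type IPC values: per-cluster means (default) or raw pairs."""
    values: dict[str, list[float]] = {t: [] for t in PAIR_TYPES}
    if mode == "cluster_means":
        for s in summaries:
            for t in PAIR_TYPES:
                v = s.mean_ipc.get(t)
                if v is not None:
                    values[t].append(v)
    elif mode == "pairs":
        if rows is None:
            raise StatsError("pair mode needs the pair-level rows")
        for r in rows:
            if r.ipc is not None:
                values[r.pair_type].append(r.ipc)
    else:
        raise ValueError(f"unknown MWW mode {mode!r}")
    return values


def compare_pair_types(
    summaries: Sequence[ClusterSummary],
    rows: Sequence[PairScore],
    bins: int = 10,
    bootstrap_threshold: float = 90.0,
    mww_mode: str = "cluster_means",
) -> dict:
    """Assemble the per-comparison statistical report as a plain dict."""
    values = mean_ipc_by_type(summaries, mode=mww_mode, rows=rows)
    report: dict = {
        "n_clusters": len(summaries),
        "n_multi_clusters": sum(1 for s in summaries if s.is_multi),
        "mean_ipc": {
            t: (fmean(v) if v else None) for t, v in values.items()
        },
        "n_values": {t: len(v) for t, v in values.items()},
        "mww_p": {},
        "binning": {},
        "spearman": spearman_by_type(rows),
    }
    for label, (t1, t2) in {
        "o-o_vs_o-cno": ("o-o", "o-cno"),
        "i-i_vs_i-cni": ("i-i", "i-cni"),
    }.items():
        xs, ys = values[t1], values[t2]
        report["mww_p"][label] = mww_test(xs, ys) if xs and ys else None
        pairs1 = [(r.identity, r.ipc) for r in rows if r.pair_type == t1 and r.ipc is not None]
        pairs2 = [(r.identity, r.ipc) for r in rows if r.pair_type == t2 and r.ipc is not None]
        if len(pairs1) >= bins and len(pairs2) >= bins:
            combined, b1, b2 = combined_bin_boundaries(
                [p[0] for p in pairs1], [p[0] for p in pairs2], bins
            )
            spec = binned_log2_ratio(pairs1, pairs2, combined)
            spec.boundaries_type1 = b1
            spec.boundaries_type2 = b2
            report["binning"][label] = {
                "boundaries": spec.boundaries,
                "mean_ipc_type1": spec.mean_ipc_type1,
                "mean_ipc_type2": spec.mean_ipc_type2,
                "counts_type1": spec.counts_type1,
                "counts_type2": spec.counts_type2,
                "log2_ratio": spec.log2_ratio,
            }
        else:
            report["binning"][label] = None
    agreement = agreement_by_bootstrap(summaries, threshold=bootstrap_threshold)
    report["agreement_by_bootstrap"] = {
        "threshold": agreement.threshold,
        "fraction_high": agreement.fraction_high,
        "fraction_low": agreement.fraction_low,
        "n_high": agreement.n_high,
        "n_low": agreement.n_low,
        "n_unknown_bootstrap": agreement.n_unknown_bootstrap,
    }
    return report
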