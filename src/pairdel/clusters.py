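"""Enhancer-cluster aggregation.

Individual enhancers with redundant functions may each fall short of the
single-region significance threshold while the cluster's combined effect
is clear.  Two complementary statistics are computed at cluster
granularity: a weighted Kolmogorov-Smirnov enrichment score over
region-level depletion scores (GSEA-style, label permutations) and the
alpha-RRA score over the pooled guide pairs of the cluster's members.
The shared top-k clusters of the two methods are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .models import TargetRegion
from .screen import alpha_rra


@dataclass(frozen=True)
class EnhancerCluster:
    cluster_id: str
    members: tuple[str, ...]
    chrom: str = ""
    start: int = 0
    end: int = 0


def map_regions_to_clusters(regions: list[TargetRegion],
                            cluster_intervals: list[tuple[str, str, int, int]]
                            ) -> tuple[list[EnhancerCluster], list[str]]:
    """Assign regions to the cluster interval containing their midpoint.

    ``cluster_intervals`` rows are (cluster_id, chrom, start, end),
    half-open.  Overlapping cluster intervals are an ambiguous annotation
    and raise.  Returns (clusters, unassigned region_ids); unassigned
    regions are excluded from cluster testing.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for cid, chrom, start, end in cluster_intervals:
        by_chrom.setdefault(chrom, []).append((start, end, cid))
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        for (s1, e1, c1), (s2, e2, c2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping cluster intervals {c1} and {c2} on {chrom}")
    members: dict[str, list[str]] = {}
    unassigned: list[str] = []
    for region in regions:
        mid = region.midpoint
        hit = None
        for s, e, cid in by_chrom.get(region.chrom, ()):  # sorted, few per chrom
            if s <= mid < e:
                hit = cid
                break
        if hit is None:
            unassigned.append(region.region_id)
        else:
            members.setdefault(hit, []).append(region.region_id)
    span = {cid: (chrom, s, e)
            for cid, chrom, s, e in cluster_intervals}
    clusters = [EnhancerCluster(cid, tuple(sorted(ms)), *span[cid])
                for cid, ms in sorted(members.items())]
    return clusters, unassigned


def _enrichment_score(in_set: np.ndarray, weights: np.ndarray) -> float:
    """Signed extremum of the weighted KS running sum."""
    n = len(in_set)
    k = int(in_set.sum())
    hit_total = weights[in_set].sum()
    if hit_total == 0 or k in (0, n):
        return 0.0
    step = np.where(in_set, weights / hit_total, -1.0 / (n - k))
    running = np.cumsum(step)
    return float(running[np.argmax(np.abs(running))])


def cluster_depletion_gsea(region_scores: pd.Series,
                           clusters: list[EnhancerCluster],
                           weight: float = 1.0, n_perm: int = 1000,
                           seed: int = 0) -> pd.DataFrame:
    """Weighted-KS enrichment of each cluster in the depletion ranking.

    ``region_scores`` must be oriented so depletion is high (e.g. -LFC).
    One-sided permutation p toward depletion (ES' >= ES, add-one
    smoothing), BH across clusters.  Size-1 clusters are tested but
    flagged ``small``.
    """
    scores = region_scores.sort_values(ascending=False)
    order = scores.index.to_numpy()
    weights = np.abs(scores.to_numpy()) ** weight
    pos = {r: i for i, r in enumerate(order)}
    rng = np.random.default_rng(seed)
    n = len(order)
    rows = []
    null_by_k: dict[int, np.ndarray] = {}  # null ES depends only on cluster size
    for cluster in clusters:
        idx = [pos[r] for r in cluster.members if r in pos]
        if not idx:
            continue
        in_set = np.zeros(n, dtype=bool)
        in_set[idx] = True
        es = _enrichment_score(in_set, weights)
        k = len(idx)
        if k not in null_by_k:
            null = np.empty(n_perm)
            for i in range(n_perm):
                perm = np.zeros(n, dtype=bool)
                perm[rng.choice(n, size=k, replace=False)] = True
                null[i] = _enrichment_score(perm, weights)
            null_by_k[k] = null
        p = (1 + int((null_by_k[k] >= es).sum())) / (n_perm + 1)
        rows.append((cluster.cluster_id, k, es, p, k < 2))
    out = pd.DataFrame(rows, columns=["cluster_id", "k", "es", "p", "small"])
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    return out.set_index("cluster_id")


def cluster_depletion_rra(ranks: pd.DataFrame, region_map: dict[str, str],
                          clusters: list[EnhancerCluster], alpha: float = 0.25,
                          n_perm: int = 1000, seed: int = 0,
                          cutoff: float = 0.01) -> pd.DataFrame:
    """alpha-RRA over the pooled guide pairs of each cluster's members."""
    cluster_of_region = {}
    for cluster in clusters:
        for region in cluster.members:
            cluster_of_region[region] = cluster.cluster_id
    pair_to_cluster = {pair: cluster_of_region[region]
                       for pair, region in region_map.items()
                       if region in cluster_of_region}
    out = alpha_rra(ranks, pair_to_cluster, alpha=alpha, n_perm=n_perm,
                    seed=seed, cutoff=cutoff)
    out.index.name = "cluster_id"
    return out


def select_shared_top(gsea: pd.DataFrame, rra: pd.DataFrame,
                      top_k: int = 20) -> list[str]:
    """Clusters in the top-k of both rankings, ordered by joint rank sum.

    GSEA ranks by (p ascending, es descending); RRA by (p ascending, rho
    ascending).  ``top_k`` larger than the table is capped.
    """
    top_k = min(top_k, len(gsea), len(rra))
    g_order = gsea.sort_values(["p", "es"], ascending=[True, False]).index
    if "rho" in rra.columns:
        r_order = rra.sort_values(["p_perm", "rho"]).index
    else:
        r_order = rra.sort_values(["p", "es"], ascending=[True, False]).index
    g_rank = {c: i for i, c in enumerate(g_order)}
    r_rank = {c: i for i, c in enumerate(r_order)}
    shared = set(g_order[:top_k]) & set(r_order[:top_k])
    return sorted(shared, key=lambda c: (g_rank[c] + r_rank[c], c))
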