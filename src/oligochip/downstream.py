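"""Tissue-specific calling, Venn partitioning, enrichment, clustering.

A gene is specific to tissue T when it is up-regulated in T in BOTH
pairwise comparisons that involve T (three tissues, three comparisons).
Functional enrichment of a gene set against the array background uses a
two-sided Fisher exact test per annotation term with Benjamini-Hochberg
adjustment across terms.  Hybridization profiles are grouped by
agglomerative average-linkage clustering on Euclidean distances, with a
deterministic lexicographic tie-break, and exported as newick.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .normalize_de import DEGeneList, bh_adjust

__all__ = [
    "VennPartition",
    "EnrichmentResult",
    "tissue_specific",
    "venn_partition",
    "fisher_enrichment",
    "hierarchical_cluster",
    "dendrogram_to_newick",
]


@dataclass(frozen=True)
class VennPartition:
    """The 7 disjoint regions of three sets, keyed by membership string
    ('a', 'ab', 'abc', ...)."""

    regions: dict

    def sizes(self) -> dict:
        return {k: len(v) for k, v in self.regions.items()}


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int      # term hits inside the gene set
    K: int      # term hits in the background
    n: int      # gene set size
    N: int      # background size
    p: float
    p_adj: float
    direction: str  # over | under


def tissue_specific(de_lists) -> dict[str, set[str]]:
    """Per-tissue specific gene sets from three directed pairwise lists.

    Each DEGeneList's ``direction`` maps gene -> the condition it is up
    in.  The three comparisons must cover exactly three conditions, each
    appearing in two comparisons.
    """
    de_lists = list(de_lists)
    if len(de_lists) != 3:
        raise ValueError("need exactly three pairwise comparisons")
    cond_count: dict[str, int] = {}
    pair_conditions = []
    for dl in de_lists:
        conds = dl.comparison.split("_vs_")
        if len(conds) != 2:
            raise ValueError(
                f"comparison label {dl.comparison!r} not of the form A_vs_B"
            )
        pair_conditions.append(set(conds))
        for c in conds:
            cond_count[c] = cond_count.get(c, 0) + 1
    if len(cond_count) != 3 or set(cond_count.values()) != {2}:
        raise ValueError(
            f"three comparisons must cover three conditions pairwise, got {cond_count}"
        )
    for dl, conds in zip(de_lists, pair_conditions):
        stray = set(dl.direction.values()) - conds
        if stray:
            raise ValueError(
                f"comparison {dl.comparison!r} has directions outside its conditions: {sorted(stray)}"
            )
    out: dict[str, set[str]] = {c: set() for c in cond_count}
    for tissue in out:
        involving = [dl for dl, conds in zip(de_lists, pair_conditions) if tissue in conds]
        up_sets = [
            {g for g, c in dl.direction.items() if c == tissue} for dl in involving
        ]
        out[tissue] = set.intersection(*up_sets)
    return out


def venn_partition(a, b, c) -> VennPartition:
    """Disjoint regions of three gene sets; regions partition the union."""
    a, b, c = set(a), set(b), set(c)
    regions = {
        "a": a - b - c,
        "b": b - a - c,
        "c": c - a - b,
        "ab": (a & b) - c,
        "ac": (a & c) - b,
        "bc": (b & c) - a,
        "abc": a & b & c,
    }
    return VennPartition(regions=regions)


def fisher_exact_pvalue(k: int, n: int, K: int, N: int,
                        alternative: str = "two-sided") -> float:
    """Fisher exact p for the 2×2 table (k, n−k, K−k, N−n−K+k)."""
    table = [[k, n - k], [K - k, N - n - K + k]]
    return float(stats.fisher_exact(table, alternative=alternative)[1])


def fisher_enrichment(gene_set, background, term_map: pd.DataFrame,
                      alternative: str = "two-sided") -> list[EnrichmentResult]:
    """Per-term Fisher exact enrichment of ``gene_set`` vs ``background``.

    ``term_map`` columns: gene_id, term_id[, term_name].  Genes missing
    from the annotation map still count toward n and N but hit no term.
    Two-sided p-values sum all 2×2 tables at most as probable as the
    observed one; BH adjustment is across terms.
    """
    gene_set = set(gene_set)
    background = set(background)
    stray = gene_set - background
    if stray:
        raise ValueError(f"genes not in background: {sorted(stray)[:5]}")
    if not gene_set:
        return []
    n = len(gene_set)
    N = len(background)
    annotated = term_map[term_map["gene_id"].isin(background)]
    results = []
    for term_id, sub in annotated.groupby("term_id", sort=True):
        members = set(sub["gene_id"])
        K = len(members)
        k = len(members & gene_set)
        p = fisher_exact_pvalue(k, n, K, N, alternative=alternative)
        expected = n * K / N
        direction = "over" if k >= expected else "under"
        name = str(sub["term_name"].iloc[0]) if "term_name" in sub.columns else term_id
        results.append((term_id, name, k, K, p, direction))
    if not results:
        return []
    padj = bh_adjust([r[4] for r in results])
    return [
        EnrichmentResult(term_id=t, term_name=name, k=k, K=K, n=n, N=N,
                         p=float(p), p_adj=float(q), direction=direction)
        for (t, name, k, K, p, direction), q in zip(results, padj)
    ]


# ---------------------------------------------------------------------------
# Average-linkage hierarchical clustering
# ---------------------------------------------------------------------------

def hierarchical_cluster(profiles: pd.DataFrame) -> list[tuple]:
    """Agglomerative average linkage on Euclidean distances.

    ``profiles``: hybridizations (rows) × genes (columns); genes with any
    missing value are dropped.  Returns the merge list
    [(left, right, height, size), ...] where left/right are leaf labels
    or earlier merge indices prefixed 'node', and ties break on the
    lexicographically smallest label pair.
    """
    profiles = profiles.dropna(axis=1)
    labels = list(profiles.index.astype(str))
    if len(labels) < 2:
        raise ValueError("need >= 2 profiles")
    x = profiles.to_numpy(dtype=float)
    # active clusters: name -> (member row indices)
    clusters: dict[str, list[int]] = {lab: [i] for i, lab in enumerate(labels)}
    dist = {
        (la, lb): float(np.linalg.norm(x[i] - x[j]))
        for (i, la), (j, lb) in itertools.combinations(enumerate(labels), 2)
    }

    def d(u: str, v: str) -> float:
        return dist[(u, v)] if (u, v) in dist else dist[(v, u)]

    merges: list[tuple] = []
    node_count = 0
    while len(clusters) > 1:
        names = sorted(clusters)
        best = None
        for u, v in itertools.combinations(names, 2):
            cand = (d(u, v), u, v)
            if best is None or cand < best:
                best = cand
        height, u, v = best
        new_name = f"node{node_count}"
        node_count += 1
        members = clusters[u] + clusters[v]
        # average linkage: size-weighted mean of the two old distances
        for w in names:
            if w in (u, v):
                continue
            duw, dvw = d(u, w), d(v, w)
            nu, nv = len(clusters[u]), len(clusters[v])
            dist[(new_name, w)] = (nu * duw + nv * dvw) / (nu + nv)
        clusters.pop(u)
        clusters.pop(v)
        clusters[new_name] = members
        merges.append((u, v, height, len(members)))
    return merges


def dendrogram_to_newick(merges: list[tuple]) -> str:
    """Newick string with branch lengths from merge heights.

    A child's branch length is (parent height − child height)/2 on the
    ultrametric scale (leaves sit at height 0).
    """
    pos: dict[str, float] = {}      # ultrametric height of each node
    subtree: dict[str, str] = {}

    for idx, (u, v, height, _) in enumerate(merges):
        for child in (u, v):
            if child not in subtree:
                subtree[child] = child
                pos[child] = 0.0
        h = height / 2.0
        bl_u = h - pos[u]
        bl_v = h - pos[v]
        name = f"node{idx}"
        subtree[name] = f"({subtree[u]}:{bl_u:.6g},{subtree[v]}:{bl_v:.6g})"
        pos[name] = h
    root = f"node{len(merges) - 1}"
    return subtree[root] + ";"
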