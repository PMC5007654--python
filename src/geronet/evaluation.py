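"""Evaluation: AUROC of the disease ranking, baseline methods, disease-name
merging aid, and module-overlap validation against an external module set.

The ranking is judged by how well it separates age-related diseases (ARDs)
from non-ARDs: smaller scores mean "more age-connected", so the AUROC is
computed on the negated scores.  Two baselines bracket the modularized
pipeline: Direct Overlap (Jaccard index between aging and disease genes)
and Whole Network (the mutual-reachability machinery applied to the entire
reference network as a single module).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom, norm
from sklearn.metrics import roc_auc_score

from .modules import ExpandedModule
from .netio import GeneNetwork, GeneSet, LabelTable
from .reachability import ReachabilityScore, mutual_reachability
from .rwr import RWRParams
from .significance import adjust_fdr

__all__ = [
    "auroc",
    "jaccard_overlap",
    "cooccurrence_jaccard",
    "direct_overlap_scores",
    "subnetwork_overlap_scores",
    "whole_network_score",
    "merge_categories",
    "OverlapMatrix",
    "module_overlap_test",
    "overlap_count_permutation",
]


def auroc(scores: Mapping[str, float], labels: LabelTable) -> float:
    """AUROC of a per-disease score table against ARD labels.

    Smaller score = more ARD-like (scores are geometric-mean adjusted
    p-values).  Diseases without a label are ignored; diseases labeled but
    unscored are excluded by default (see ``pessimize_unscored`` upstream).
    """
    diseases = [d for d in sorted(scores) if d in labels]
    if not diseases:
        raise ValueError("no scored disease carries a label")
    y = np.array([labels[d] for d in diseases], dtype=int)
    if y.min() == y.max():
        raise ValueError("labels are single-class; AUROC undefined")
    s = np.array([scores[d] for d in diseases], dtype=float)
    return float(roc_auc_score(y, -s))


def jaccard_overlap(a: GeneSet, b: GeneSet) -> float:
    """|a ∩ b| / |a ∪ b| of two gene sets."""
    union = a.genes | b.genes
    if not union:
        raise ValueError("both sets empty")
    return len(a.genes & b.genes) / len(union)


def cooccurrence_jaccard(ids_disease: set, ids_anchor: set) -> float:
    """Jaccard index of two publication-identifier sets — the literature
    co-occurrence statistic (e.g. PubMed IDs mentioning a disease vs. those
    mentioning ageing).  Retrieval of the identifier sets is the caller's
    concern; this is the pure set statistic."""
    union = set(ids_disease) | set(ids_anchor)
    if not union:
        raise ValueError("both identifier sets empty")
    return len(set(ids_disease) & set(ids_anchor)) / len(union)


def direct_overlap_scores(
    aging: GeneSet, diseases: Sequence[GeneSet]
) -> dict[str, float]:
    """Direct Overlap baseline: score = 1 - Jaccard(aging, disease), so
    smaller is more age-connected, matching the pipeline's convention."""
    return {d.name: 1.0 - jaccard_overlap(aging, d) for d in diseases}


def whole_network_score(
    net: GeneNetwork,
    aging: GeneSet,
    disease: GeneSet,
    beta: float = 0.1,
    params: RWRParams = RWRParams(),
) -> ReachabilityScore:
    """Whole Network baseline: mutual reachability with the entire reference
    network standing in as the single expanded module."""
    mapped_aging = net.map_genes(aging.genes)
    mapped_disease = net.map_genes(disease.genes)
    if len(mapped_aging) < 5 or len(mapped_disease) < 5:
        raise ValueError("need >=5 mapped genes from each set on the whole network")
    emn = ExpandedModule(
        name="whole_network",
        seed_genes=GeneSet("whole_network", net.nodes),
        member_genes=list(net.nodes),
        subnetwork=net,
        expansion_fold=1,
        cap=net.n,
    )
    return mutual_reachability(emn, aging, disease, beta=beta, params=params)


def subnetwork_overlap_scores(
    emns: Sequence[ExpandedModule],
    aging: GeneSet,
    diseases: Sequence[GeneSet],
    background_n: int,
    min_genes: int = 5,
) -> dict[str, float]:
    """Subnetwork Direct Overlap baseline: within each applicable eMN, test
    the overlap of the mapped aging and disease genes by one-sided Fisher
    exact test against the eMN membership; BH-adjust the pooled family and
    score each disease by the geometric mean of its adjusted p-values."""
    rows: list[tuple[str, float]] = []
    for disease in diseases:
        for emn in emns:
            members = emn.member_set()
            a = aging.genes & members
            d = disease.genes & members
            if len(a) < min_genes or len(d) < min_genes:
                continue
            p = fisher_enrichment_p(len(a & d), len(a), len(d), len(members))
            rows.append((disease.name, p))
    if not rows:
        return {}
    fdrs = adjust_fdr([p for _, p in rows])
    frame = pd.DataFrame({"disease": [d for d, _ in rows], "fdr": fdrs})
    return {
        d: float(np.exp(np.mean(np.log(np.maximum(g["fdr"].to_numpy(), 1e-300)))))
        for d, g in frame.groupby("disease")
    }


def merge_categories(sets: Sequence[GeneSet], cut_height: float) -> list[list[str]]:
    """Candidate disease-category merges by average-linkage hierarchical
    clustering on the 1 - Jaccard distance between gene sets, cut at
    ``cut_height``.  The merge decision itself stays manual; this returns
    the clusters (lists of set names) as suggestions."""
    if len(sets) < 2:
        raise ValueError("need at least two sets to cluster")
    n = len(sets)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = 1.0 - jaccard_overlap(sets[i], sets[j])
    linkage = sch.linkage(squareform(dist, checks=False), method="average")
    assignment = sch.fcluster(linkage, t=cut_height, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for s, c in zip(sets, assignment):
        clusters.setdefault(int(c), []).append(s.name)
    return [sorted(v) for _, v in sorted(clusters.items())]


def fisher_enrichment_p(overlap: int, size_a: int, size_b: int, background: int) -> float:
    """One-sided (enrichment) Fisher exact p for an overlap of two sets in a
    common background — the upper hypergeometric tail P(X >= overlap)."""
    if size_a > background or size_b > background:
        raise ValueError("set larger than the background universe")
    return float(hypergeom.sf(overlap - 1, background, size_a, size_b))


@dataclass
class OverlapMatrix:
    """Pairwise Fisher enrichment of two module collections over a shared
    gene background, with BH adjustment over the full matrix."""

    rows: list[str]
    cols: list[str]
    pvalues: np.ndarray
    fdr: np.ndarray
    background_n: int

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        return self.fdr <= alpha


def module_overlap_test(
    c1: Sequence[GeneSet], c2: Sequence[GeneSet], background_n: int
) -> OverlapMatrix:
    p = np.empty((len(c1), len(c2)))
    for i, a in enumerate(c1):
        for j, b in enumerate(c2):
            p[i, j] = fisher_enrichment_p(
                len(a.genes & b.genes), len(a), len(b), background_n
            )
    fdr = adjust_fdr(np.clip(p.ravel(), 1e-300, 1.0)).reshape(p.shape)
    return OverlapMatrix([s.name for s in c1], [s.name for s in c2], p, fdr, background_n)


def overlap_count_permutation(
    c1_top: Sequence[GeneSet],
    c2_full: Sequence[GeneSet],
    c2_top_names: Sequence[str],
    background_n: int,
    n_perm: int = 1000,
    rng_seed: int | None = None,
    alpha: float = 0.05,
) -> tuple[float, float, float, int]:
    """Permutation significance of the count of ``c1_top`` modules that
    significantly overlap (BH FDR <= alpha) at least one top module of c2.

    Each replicate reshuffles gene labels across all of c2's modules holding
    module sizes fixed, rebuilds c2's top modules from the reshuffled
    labels, and recounts.  Returns (null_mean, null_sd, one-tailed normal p
    of the observed count, observed count).
    """
    if n_perm < 2:
        raise ValueError("need at least 2 permutation replicates")
    rng = np.random.default_rng(rng_seed)
    top_names = set(c2_top_names)

    def count_hits(c2_top: Sequence[GeneSet]) -> int:
        om = module_overlap_test(c1_top, c2_top, background_n)
        return int(om.significant(alpha).any(axis=1).sum())

    observed = count_hits([m for m in c2_full if m.name in top_names])
    pool = np.array([g for m in c2_full for g in sorted(m.genes)], dtype=object)
    sizes = [len(m) for m in c2_full]
    null = np.empty(n_perm)
    for b in range(n_perm):
        shuffled = rng.permutation(pool)
        reshuffled, start = [], 0
        for m, sz in zip(c2_full, sizes):
            if m.name in top_names:
                reshuffled.append(GeneSet(m.name, set(shuffled[start : start + sz])))
            start += sz
        null[b] = count_hits(reshuffled)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    if null_sd == 0.0:
        p = 1.0 if observed <= null_mean else 1.0 / (n_perm + 1)
    else:
        p = float(norm.sf((observed - null_mean) / null_sd))
    return null_mean, null_sd, p, observed
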