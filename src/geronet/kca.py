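"""Key connector analysis (KCA): hub genes mediating a target gene set.

Derived from key driver analysis with dynamic neighbourhood search, applied
to an undirected network, where hubs are better read as *connectors* than
drivers.  Given a target set G (here, typically the genes common to the
expanded aging and expanded disease genes of a significant eMN):

1. restrict to the subnetwork N_G of nodes within L steps of G;
2. for each candidate gene g in N_G and each layer h = 1..H, take the genes
   at distance <= h from g within N_G (a ball, excluding g) and test its
   enrichment for target genes by a hypergeometric test with N_G as
   background;
3. the per-gene p is the minimum over layers; Bonferroni-correct across all
   candidates and report genes passing the threshold, most significant
   first.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.sparse.csgraph import dijkstra
from scipy.stats import hypergeom

from .netio import GeneNetwork, GeneSet

__all__ = ["KCAParams", "KeyConnector", "key_connectors"]


@dataclass(frozen=True)
class KCAParams:
    """Subnetwork radius L, maximum neighbourhood layer H, Bonferroni alpha,
    and whether layers are balls (distance <= h, default) or shells
    (distance exactly h)."""

    L: int = 2
    H: int = 2
    alpha: float = 0.05
    shell: bool = False

    def __post_init__(self):
        if self.L < 1 or self.H < 1:
            raise ValueError("L and H must be >= 1")


@dataclass
class KeyConnector:
    gene: str
    best_layer: int
    raw_p: float
    bonferroni_p: float


def key_connectors(
    net: GeneNetwork,
    target: GeneSet,
    params: KCAParams = KCAParams(),
    return_all: bool = False,
) -> list[KeyConnector]:
    """Rank candidate key connectors for ``target`` on ``net``.

    Returns connectors with Bonferroni p <= alpha sorted by (p, gene), or
    every tested candidate when ``return_all`` (for inspection/ranking).
    Target genes themselves are eligible candidates: a hub inside the
    target set is still a connector.
    """
    mapped = net.map_genes(target.genes)
    if len(mapped) < 2:
        raise ValueError("target must map to at least 2 network nodes")
    target_idx = np.array([net.index[g] for g in mapped], dtype=int)

    adj = net.adjacency
    dist_from_targets = dijkstra(
        adj, directed=False, unweighted=True, indices=target_idx, limit=params.L
    )
    in_ball = np.isfinite(dist_from_targets).any(axis=0)
    ng_nodes = np.flatnonzero(in_ball)
    if ng_nodes.size < 3:
        warnings.warn("L-ball subnetwork has fewer than 3 nodes; no candidates tested")
        return []

    sub = adj[ng_nodes][:, ng_nodes]
    names = [net.nodes[i] for i in ng_nodes]
    is_target = np.isin(ng_nodes, target_idx)
    m_bg = ng_nodes.size - 1  # background excludes the candidate itself

    dist = dijkstra(sub, directed=False, unweighted=True, limit=params.H)
    results: list[KeyConnector] = []
    for gi in range(ng_nodes.size):
        k_targets = int(is_target.sum()) - int(is_target[gi])
        if k_targets == 0:
            continue
        best_p, best_h = 1.0, params.H
        for h in range(1, params.H + 1):
            if params.shell:
                neigh = (dist[gi] == h)
            else:
                neigh = (dist[gi] <= h)
            neigh[gi] = False
            n_draw = int(neigh.sum())
            if n_draw == 0:
                continue
            hits = int((neigh & is_target).sum())
            p = float(hypergeom.sf(hits - 1, m_bg, k_targets, n_draw))
            if p < best_p:
                best_p, best_h = p, h
        results.append(KeyConnector(names[gi], best_h, best_p, min(1.0, best_p * ng_nodes.size)))

    results.sort(key=lambda kc: (kc.bonferroni_p, kc.raw_p, kc.gene))
    if return_all:
        return results
    return [kc for kc in results if kc.bonferroni_p <= params.alpha]
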