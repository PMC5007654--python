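"""GSEA-like mutual reachability between two gene sets on an eMN.

Two random walks are run on the expanded module's subnetwork: one seeded
with the mapped disease genes, one with the mapped aging genes.  Each walk
ranks all eMN genes; a Kolmogorov–Smirnov-style running sum then scores how
early the *other* set appears in the ranking.  Walking the ranked list, a
hit adds ``+1/G`` and a miss adds ``-1/(N - G)`` (``N`` eMN genes, ``G``
hits), so the curve always returns to zero; its peak is the enrichment
score.  The two directions combine as

    ES_beta = beta * ES1 + (1 - beta) * ES2

with ES1 the disease-seeded walk scored against aging genes and ES2 the
aging-seeded walk scored against disease genes.  Genes up to each peak are
the "expanded" disease/aging genes — the leading edge of the reachability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .modules import ExpandedModule
from .netio import GeneSet
from .rwr import RWRParams, RWRSolver, rank_order

__all__ = ["ReachabilityScore", "running_sum", "mutual_reachability"]


@dataclass
class ReachabilityScore:
    """Both directional enrichment scores and their beta-weighted combination
    for one (disease, eMN) pair."""

    es1: float
    es2: float
    es_beta: float
    beta: float
    expanded_disease_genes: GeneSet
    expanded_aging_genes: GeneSet
    n_members: int
    n_aging_mapped: int
    n_disease_mapped: int
    n_overlap: int


def running_sum(
    ranked: list[str], hits: GeneSet | frozenset[str] | set[str]
) -> tuple[np.ndarray, float, int]:
    """Running-sum enrichment of ``hits`` along a ranked gene list.

    Returns the cumulative curve, its maximum (the enrichment score) and the
    peak position counted in genes, so ``ranked[:peak]`` is the
    leading-edge prefix ("visited genes" up to the peak); the first position
    attaining the maximum is reported when the peak value ties.
    """
    hit_genes = hits.genes if isinstance(hits, GeneSet) else hits
    indicator = np.fromiter((g in hit_genes for g in ranked), dtype=bool, count=len(ranked))
    curve, es, peak = _running_sum_from_indicator(indicator)
    return curve, es, peak


def _running_sum_from_indicator(indicator: np.ndarray) -> tuple[np.ndarray, float, int]:
    nn = indicator.shape[0]
    gg = int(indicator.sum())
    if gg == 0 or gg == nn:
        raise ValueError(
            f"running sum undefined: {gg} hits among {nn} ranked genes "
            "(need 0 < hits < total)"
        )
    incr = np.where(indicator, 1.0 / gg, -1.0 / (nn - gg))
    curve = np.cumsum(incr)
    argpeak = int(np.argmax(curve))
    return curve, float(curve[argpeak]), argpeak + 1


def _es_batch(order: np.ndarray, indicator: np.ndarray) -> np.ndarray:
    """Enrichment scores for a batch of rankings over a shared gene universe.

    ``order`` is (n_genes, n_rankings) of member indices per column;
    ``indicator`` is either a single boolean hit vector over members or a
    (n_genes, n_rankings) boolean matrix of per-ranking hit sets.
    """
    if indicator.ndim == 1:
        hits = indicator[order]
    else:
        hits = np.take_along_axis(indicator, order, axis=0)
    nn = order.shape[0]
    gg = hits.sum(axis=0)
    incr = np.where(hits, 1.0 / gg, -1.0 / (nn - gg))
    return np.maximum.accumulate(np.cumsum(incr, axis=0), axis=0)[-1]


class PairEngine:
    """Per-eMN computation kernel shared by the observed score and its
    permutation null: caches the subnetwork's LU-factorised RWR solver, the
    lexicographic tie-break ranks and the disease-seeded ranking."""

    def __init__(self, emn: ExpandedModule, restart: float = 0.7):
        self.emn = emn
        self.net = emn.subnetwork
        self.solver = RWRSolver(self.net, restart)
        nodes = np.asarray(self.net.nodes, dtype=object)
        lex = np.argsort(nodes)
        self.lex_rank = np.empty(len(nodes), dtype=int)
        self.lex_rank[lex] = np.arange(len(nodes))

    def indices(self, genes: GeneSet | set[str]) -> np.ndarray:
        gs = genes.genes if isinstance(genes, GeneSet) else genes
        return np.array(sorted(self.net.index[g] for g in gs if g in self.net.index), dtype=int)

    def propagate(self, seed_idx: np.ndarray) -> np.ndarray:
        p0 = np.zeros(self.net.n)
        p0[seed_idx] = 1.0 / seed_idx.size
        return self.solver.solve(p0)

    def ranking(self, seed_idx: np.ndarray) -> np.ndarray:
        """Member indices ordered by descending steady-state probability,
        lexicographic gene name on ties."""
        p = self.propagate(seed_idx)
        return np.lexsort((self.lex_rank, -np.round(p, 12)))

    def propagate_batch(self, seed_idx_matrix: np.ndarray) -> np.ndarray:
        """Steady states for many seed sets at once (columns of the result)."""
        n_sets, m = seed_idx_matrix.shape
        p0 = np.zeros((self.net.n, n_sets))
        p0[seed_idx_matrix.T, np.arange(n_sets)[None, :].repeat(m, axis=0)] = 1.0 / m
        return self.solver.solve(p0)

    def rank_batch(self, probabilities: np.ndarray) -> np.ndarray:
        out = np.empty_like(probabilities, dtype=int)
        quant = -np.round(probabilities, 12)
        for j in range(probabilities.shape[1]):
            out[:, j] = np.lexsort((self.lex_rank, quant[:, j]))
        return out


def mutual_reachability(
    emn: ExpandedModule,
    aging: GeneSet,
    disease: GeneSet,
    beta: float = 0.1,
    params: RWRParams = RWRParams(),
    engine: PairEngine | None = None,
) -> ReachabilityScore:
    """Mutual reachability score of aging and disease genes on one eMN.

    Genes in both sets count as hits in both directions: shared genes are
    the strongest evidence of an aging–disease connection, not a nuisance.
    """
    if not 0.0 < beta < 1.0:
        raise ValueError("beta must be in (0, 1)")
    if engine is None:
        engine = PairEngine(emn, params.restart)
    nodes = engine.net.nodes
    aging_idx = engine.indices(aging)
    disease_idx = engine.indices(disease)
    if aging_idx.size == 0 or disease_idx.size == 0:
        raise ValueError("aging and disease genes must both map to the eMN")

    aging_mask = np.zeros(len(nodes), dtype=bool)
    aging_mask[aging_idx] = True
    disease_mask = np.zeros(len(nodes), dtype=bool)
    disease_mask[disease_idx] = True

    order_d = engine.ranking(disease_idx)
    curve1, es1, peak1 = _running_sum_from_indicator(aging_mask[order_d])
    expanded_disease = GeneSet(
        f"{disease.name}|{emn.name}|expanded", {nodes[i] for i in order_d[:peak1]}
    )

    order_a = engine.ranking(aging_idx)
    curve2, es2, peak2 = _running_sum_from_indicator(disease_mask[order_a])
    expanded_aging = GeneSet(
        f"{aging.name}|{emn.name}|expanded", {nodes[i] for i in order_a[:peak2]}
    )

    return ReachabilityScore(
        es1=es1,
        es2=es2,
        es_beta=beta * es1 + (1.0 - beta) * es2,
        beta=beta,
        expanded_disease_genes=expanded_disease,
        expanded_aging_genes=expanded_aging,
        n_members=len(nodes),
        n_aging_mapped=int(aging_idx.size),
        n_disease_mapped=int(disease_idx.size),
        n_overlap=int((aging_mask & disease_mask).sum()),
    )
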