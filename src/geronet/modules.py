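"""Modularized networks (MN) and their RWR expansions (eMN).

A gene set (GO BP / KEGG pathway) mapped onto the reference network defines
a modularized network.  Seeding an RWR with all mapped members and taking
the top ``min(cap, fold * n_seeds)`` ranked genes yields the expanded
modularized network: the induced subgraph of the reference network on those
genes.  Expansion guarantees each module subnetwork is large and connected
enough for the reachability analysis downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .netio import GeneNetwork, GeneSet
from .rwr import RWRParams, RWRSolver, rank_order

__all__ = [
    "ExpandedModule",
    "filter_gene_sets",
    "expand_module",
    "dedupe_modules",
    "applicable_pairs",
    "remove_redundant_sets",
]


@dataclass
class ExpandedModule:
    """One eMN: seed provenance plus the induced subnetwork.

    ``member_genes`` is ordered by RWR rank (seeds first in practice, since
    restart mass concentrates on them); ``subnetwork`` carries exactly the
    reference-network edges among the members.
    """

    name: str
    seed_genes: GeneSet
    member_genes: list[str]
    subnetwork: GeneNetwork
    expansion_fold: int
    cap: int

    @property
    def size(self) -> int:
        return len(self.member_genes)

    def member_set(self) -> frozenset[str]:
        return frozenset(self.member_genes)


def filter_gene_sets(
    sets: list[GeneSet], min_size: int = 30, max_size: int = 500
) -> list[GeneSet]:
    """Keep sets with min_size <= |genes| <= max_size (bounds inclusive)."""
    return [s for s in sets if min_size <= len(s) <= max_size]


def expand_module(
    net: GeneNetwork,
    module: GeneSet,
    fold: int = 4,
    cap: int = 500,
    params: RWRParams = RWRParams(),
    solver: RWRSolver | None = None,
) -> ExpandedModule | None:
    """RWR-expand a module on the reference network.

    Returns ``None`` (with a warning) when no module gene maps to the
    network; such modules are excluded downstream.  ``fold`` multiplies the
    *mapped* module size; the cap (default 500) wins when smaller.
    """
    mapped = net.map_genes(module.genes)
    if not mapped:
        warnings.warn(f"module {module.name!r}: no gene maps to the network; skipped")
        return None
    if solver is None:
        solver = RWRSolver(net, params.restart)
    result = solver.solve_seeds(mapped)
    k = min(cap, fold * len(mapped), net.n)
    members = rank_order(result.probabilities, net.nodes)[:k]
    return ExpandedModule(
        name=module.name,
        seed_genes=GeneSet(module.name, mapped),
        member_genes=members,
        subnetwork=net.subnetwork(members),
        expansion_fold=fold,
        cap=cap,
    )


def dedupe_modules(emns: list[ExpandedModule]) -> list[ExpandedModule]:
    """Drop eMNs whose member sets duplicate an earlier eMN's."""
    seen: set[frozenset[str]] = set()
    unique = []
    for emn in emns:
        key = emn.member_set()
        if key not in seen:
            seen.add(key)
            unique.append(emn)
    return unique


def applicable_pairs(
    emns: list[ExpandedModule],
    aging: GeneSet,
    diseases: list[GeneSet],
    min_genes: int = 5,
) -> list[tuple[GeneSet, ExpandedModule]]:
    """(disease, eMN) pairs where the eMN holds at least ``min_genes`` aging
    genes and ``min_genes`` disease genes."""
    pairs = []
    members = [emn.member_set() for emn in emns]
    aging_counts = [len(aging.genes & m) for m in members]
    for disease in diseases:
        for emn, m, n_aging in zip(emns, members, aging_counts):
            if n_aging >= min_genes and len(disease.genes & m) >= min_genes:
                pairs.append((disease, emn))
    return pairs


def remove_redundant_sets(
    sets: list[GeneSet], jaccard_threshold: float = 0.8
) -> list[GeneSet]:
    """Greedy redundancy removal over sets sorted by descending size.

    A set is kept iff its Jaccard index with every previously kept set stays
    below the threshold.  Size ties broken by name for determinism.
    """
    if not 0.0 < jaccard_threshold <= 1.0:
        raise ValueError("jaccard_threshold must be in (0, 1]")
    ordered = sorted(sets, key=lambda s: (-len(s), s.name))
    kept: list[GeneSet] = []
    for cand in ordered:
        if all(cand.jaccard(k) < jaccard_threshold for k in kept):
            kept.append(cand)
    return kept
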