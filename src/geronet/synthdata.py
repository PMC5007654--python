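"""Synthetic benchmark generator with planted aging–disease connectivity.

Emulates the five inputs of the pipeline — reference PPI network, module
collection, aging gene list, per-disease gene sets, and ARD labels — with a
tunable planted signal.  The construction mirrors the structure the method
assumes in real data:

* a scale-free (Barabási–Albert) network, since PPI degree distributions
  are heavy-tailed and RWR exploits hub structure;
* modules as connected neighbourhoods around random anchor genes, sized to
  survive the 30–500 module filter;
* aging genes concentrated in a few "aging-heavy" modules;
* each age-related disease (ARD) draws ``overlap_fraction`` of its genes
  from the aging set itself, ``connection_strength`` of the remainder from
  the 1-hop neighbourhood of aging genes inside the aging-heavy modules,
  and the rest uniformly; non-ARD genes are uniform draws.

At ``connection_strength = 0`` and ``overlap_fraction = 0`` the ARD and
non-ARD sets are exchangeable — the global null.  Gene names are
zero-padded ("g000123") so lexicographic tie-breaking coincides with
numeric order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .netio import (
    GeneNetwork,
    GeneSet,
    LabelTable,
    normalize_adjacency,
    write_edge_list,
    write_gmt,
    write_labels,
)

__all__ = [
    "SynthConfig",
    "SyntheticData",
    "generate",
    "write_fixture",
    "planted_connector_instance",
]


@dataclass(frozen=True)
class SynthConfig:
    """Benchmark generator settings; defaults give the scaled signal
    condition (20 diseases, half of them ARDs, on a 500-node network where
    expanded modules stay small relative to the whole network)."""

    n_nodes: int = 500
    edge_model: str = "barabasi_albert"  # or "erdos_renyi"
    ba_attachment: int = 3
    er_mean_degree: float = 6.0
    n_modules: int = 15
    module_size_range: tuple[int, int] = (30, 40)
    n_aging_modules: int = 2
    n_diseases: int = 20
    n_ard: int = 10
    aging_set_size: int = 30
    disease_size_range: tuple[int, int] = (20, 30)
    connection_strength: float = 0.8
    overlap_fraction: float = 0.2
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_ard > self.n_diseases:
            raise ValueError("n_ard cannot exceed n_diseases")
        if self.aging_set_size > self.n_nodes:
            raise ValueError("aging_set_size exceeds n_nodes")
        if not 0.0 <= self.connection_strength <= 1.0:
            raise ValueError("connection_strength must be in [0, 1]")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if min(self.module_size_range) < 1 or min(self.disease_size_range) < 1:
            raise ValueError("sizes must be positive")
        if self.module_size_range[0] > self.n_nodes:
            raise ValueError("module size exceeds n_nodes")
        if self.edge_model not in ("barabasi_albert", "erdos_renyi"):
            raise ValueError(f"unknown edge_model {self.edge_model!r}")


@dataclass
class SyntheticData:
    network: GeneNetwork
    modules: list[GeneSet]
    aging: GeneSet
    diseases: list[GeneSet]
    labels: LabelTable
    config: SynthConfig

    @property
    def ard_names(self) -> list[str]:
        return sorted(d for d in self.labels if self.labels[d])


def _gene_name(i: int) -> str:
    return f"g{i:06d}"


def _make_graph(cfg: SynthConfig, rng: np.random.Generator) -> GeneNetwork:
    seed = int(rng.integers(0, 2**31 - 1))
    if cfg.edge_model == "barabasi_albert":
        g = nx.barabasi_albert_graph(cfg.n_nodes, cfg.ba_attachment, seed=seed)
    else:
        p = min(1.0, cfg.er_mean_degree / max(1, cfg.n_nodes - 1))
        g = nx.gnp_random_graph(cfg.n_nodes, p, seed=seed)
    edges = [(_gene_name(a), _gene_name(b)) for a, b in g.edges()]
    nodes = [_gene_name(i) for i in range(cfg.n_nodes)]
    net = GeneNetwork.from_edges(edges, extra_nodes=nodes)
    return normalize_adjacency(net)


def _neighbourhood_module(
    net: GeneNetwork, anchor: str, size: int, rng: np.random.Generator
) -> set[str]:
    """Connected BFS neighbourhood of ``anchor``; layers shuffled so equal-
    distance genes enter in random order.  Falls back to uniform fill when
    the component is too small."""
    adj = net.adjacency
    chosen = [anchor]
    seen = {anchor}
    frontier = [anchor]
    while len(chosen) < size and frontier:
        nxt: set[str] = set()
        for g in frontier:
            row = adj[net.index[g]].indices
            nxt.update(net.nodes[i] for i in row)
        nxt -= seen
        layer = sorted(nxt)
        rng.shuffle(layer)
        take = layer[: size - len(chosen)]
        chosen.extend(take)
        seen.update(layer)
        frontier = take
    if len(chosen) < size:
        rest = sorted(set(net.nodes) - set(chosen))
        fill = rng.choice(len(rest), size=size - len(chosen), replace=False)
        chosen.extend(rest[i] for i in fill)
    return set(chosen)


def _sample(pool: list[str], k: int, rng: np.random.Generator) -> list[str]:
    if k <= 0 or not pool:
        return []
    k = min(k, len(pool))
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in idx]


def generate(config: SynthConfig = SynthConfig()) -> SyntheticData:
    """Generate one benchmark instance, fully reproducible from
    ``config.rng_seed``."""
    rng = np.random.default_rng(config.rng_seed)
    net = _make_graph(config, rng)
    nodes_sorted = sorted(net.nodes)

    modules: list[GeneSet] = []
    lo, hi = config.module_size_range
    for m in range(config.n_modules):
        size = int(rng.integers(lo, hi + 1))
        anchor = nodes_sorted[int(rng.integers(0, net.n))]
        modules.append(GeneSet(f"M{m:03d}", _neighbourhood_module(net, anchor, size, rng)))

    aging_idx = rng.choice(config.n_modules, size=min(config.n_aging_modules, config.n_modules), replace=False)
    aging_union = sorted(set().union(*(modules[i].genes for i in sorted(aging_idx))))
    aging_genes = _sample(aging_union, config.aging_set_size, rng)
    if len(aging_genes) < config.aging_set_size:
        rest = sorted(set(nodes_sorted) - set(aging_genes))
        aging_genes += _sample(rest, config.aging_set_size - len(aging_genes), rng)
    aging = GeneSet("aging", set(aging_genes))

    # 1-hop neighbours of aging genes inside the aging-heavy modules
    adj = net.adjacency
    neigh: set[str] = set()
    union_set = set(aging_union)
    for g in aging.genes:
        for i in adj[net.index[g]].indices:
            neigh.add(net.nodes[i])
    conn_pool = sorted((neigh & union_set) - aging.genes)

    diseases: list[GeneSet] = []
    labels: dict[str, bool] = {}
    dlo, dhi = config.disease_size_range
    for d in range(config.n_diseases):
        is_ard = d < config.n_ard
        name = f"D{d:03d}"
        size = int(rng.integers(dlo, dhi + 1))
        genes: set[str] = set()
        if is_ard:
            n_ov = round(config.overlap_fraction * size)
            genes.update(_sample(sorted(aging.genes), n_ov, rng))
            n_conn = round(config.connection_strength * (size - len(genes)))
            genes.update(_sample([g for g in conn_pool if g not in genes], n_conn, rng))
        remainder = sorted(set(nodes_sorted) - genes)
        genes.update(_sample(remainder, size - len(genes), rng))
        diseases.append(GeneSet(name, genes))
        labels[name] = is_ard

    return SyntheticData(net, modules, aging, diseases, LabelTable(labels), config)


def planted_connector_instance(
    rng_seed: int,
    cluster_size: int = 10,
    n_connector_links: int = 3,
) -> tuple[GeneNetwork, GeneSet, str]:
    """Two sparse gene clusters (an "aging" and a "disease" cluster) joined
    by a single planted articulation gene — the fixture for key connector
    analysis.

    Each cluster is a ring with a few random chords; every cluster gene
    additionally carries one or two pendant background genes, which dilute
    the neighbourhood enrichment of ordinary cluster members.  The planted
    connector links ``n_connector_links`` genes in each cluster and has no
    pendants, so its layered neighbourhood is enriched for the cluster
    union far beyond any within-cluster gene.  Returns (network, target
    gene set = cluster union, connector name).
    """
    rng = np.random.default_rng(rng_seed)
    edges: list[tuple[str, str]] = []
    clusters: dict[str, list[str]] = {}
    for label in ("a", "b"):
        names = [f"{label}{i:02d}" for i in range(cluster_size)]
        clusters[label] = names
        for i in range(cluster_size):
            edges.append((names[i], names[(i + 1) % cluster_size]))
        for _ in range(cluster_size // 3):  # random chords
            i, j = rng.choice(cluster_size, size=2, replace=False)
            edges.append((names[i], names[j]))
        for i, g in enumerate(names):  # pendant background genes
            for k in range(int(rng.integers(1, 3))):
                edges.append((g, f"p_{label}{i:02d}_{k}"))
    connector = "connector"
    for label in ("a", "b"):
        picks = rng.choice(cluster_size, size=n_connector_links, replace=False)
        for i in picks:
            edges.append((connector, clusters[label][i]))
    net = normalize_adjacency(GeneNetwork.from_edges(edges))
    target = GeneSet("cluster_union", set(clusters["a"]) | set(clusters["b"]))
    return net, target, connector


def write_fixture(data: SyntheticData, outdir) -> dict[str, Path]:
    """Write the instance in exactly the formats the readers consume, so
    fixtures exercise the real I/O path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": outdir / "network.tsv",
        "modules": outdir / "modules.gmt",
        "aging": outdir / "aging.txt",
        "diseases": outdir / "diseases.gmt",
        "labels": outdir / "labels.tsv",
    }
    write_edge_list(data.network, paths["network"])
    write_gmt(data.modules, paths["modules"])
    with open(paths["aging"], "w") as fh:
        for g in sorted(data.aging.genes):
            fh.write(g + "\n")
    write_gmt(data.diseases, paths["diseases"])
    write_labels(data.labels, paths["labels"])
    return paths
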