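"""The GeroNet model: aging–disease connection on modularized networks.

Usage follows the model/results convention::

    model = GeroNet(network, modules, aging, diseases, labels=labels)
    results = model.fit(seed=1)
    print(results.summary())
    results.ranking        # per-disease geometric-mean FDR and rank
    results.pairs          # per (disease, eMN) ES/z/p/FDR table

``fit`` executes the pipeline: filter the module collection, RWR-expand
each module into an eMN, select applicable (disease, eMN) pairs, score
mutual reachability with a permutation null per pair, BH-adjust the pooled
family, aggregate per disease by geometric mean, rank, and (when labels are
supplied) compute the AUROC of ARD recovery.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import evaluation, modules as modmod, netio, significance
from .kca import KCAParams, KeyConnector, key_connectors
from .modules import ExpandedModule
from .netio import GeneNetwork, GeneSet, LabelTable
from .reachability import PairEngine, mutual_reachability
from .rwr import RWRParams, RWRSolver

logger = logging.getLogger("geronet")

__all__ = ["GeroNet", "GeroNetResults"]


class GeroNet:
    """Model of the connection between an anchor ("aging") gene set and many
    query ("disease") gene sets across expanded network modules.

    Parameters
    ----------
    network
        Reference PPI network (undirected, binary adjacency).
    module_sets
        Candidate functional gene sets (GO BP / KEGG style).
    aging, diseases
        Anchor set and query sets.
    labels
        Optional ARD labels; enables AUROC evaluation in the results.
    expansion_fold, cap
        eMN size rule: top ``min(cap, fold * mapped module size)`` RWR-ranked
        genes (defaults 4 and 500).
    beta
        Weight of the disease-seeded enrichment score in ES_beta
        (default 0.1).
    n_perm
        Permutation replicates per pair (default 100).
    restart, tolerance
        RWR parameters (defaults 0.7 and 1e-6).
    min_module_size, max_module_size
        Module collection filter (defaults 30 and 500, inclusive).
    min_mapped_genes
        Minimum mapped aging and disease genes for an applicable pair
        (default 5).
    redundancy_threshold
        Optional Jaccard threshold for greedy module de-redundancy
        (None = keep all).
    fdr_family
        "pooled" adjusts all pairs jointly; "per-disease" adjusts within
        each disease.
    p_mode
        "normal" (z-based one-sided p) or "empirical".
    """

    def __init__(
        self,
        network: GeneNetwork,
        module_sets: Sequence[GeneSet],
        aging: GeneSet,
        diseases: Sequence[GeneSet],
        labels: LabelTable | None = None,
        *,
        expansion_fold: int = 4,
        cap: int = 500,
        beta: float = 0.1,
        n_perm: int = 100,
        restart: float = 0.7,
        tolerance: float = 1e-6,
        min_module_size: int = 30,
        max_module_size: int = 500,
        min_mapped_genes: int = 5,
        redundancy_threshold: float | None = None,
        fdr_family: str = "pooled",
        p_mode: str = "normal",
    ):
        if fdr_family not in ("pooled", "per-disease"):
            raise ValueError(f"unknown fdr_family {fdr_family!r}")
        self.network = netio.normalize_adjacency(network) if network.transition is None else network
        self.module_sets = list(module_sets)
        self.aging = aging
        self.diseases = sorted(diseases, key=lambda d: d.name)
        self.labels = labels
        self.params = dict(
            expansion_fold=expansion_fold,
            cap=cap,
            beta=beta,
            n_perm=n_perm,
            restart=restart,
            tolerance=tolerance,
            min_module_size=min_module_size,
            max_module_size=max_module_size,
            min_mapped_genes=min_mapped_genes,
            redundancy_threshold=redundancy_threshold,
            fdr_family=fdr_family,
            p_mode=p_mode,
        )

    @classmethod
    def from_files(
        cls,
        network_path,
        modules_gmt,
        aging_path,
        diseases_gmt,
        labels_path=None,
        *,
        dialect: str = "two_column",
        min_confidence: int | None = None,
        alias_map_path=None,
        **params,
    ) -> "GeroNet":
        alias = netio.read_alias_map(alias_map_path) if alias_map_path else None
        net = netio.read_edge_list(
            network_path, dialect=dialect, min_confidence=min_confidence, alias_map=alias
        )
        return cls(
            net,
            netio.read_gmt(modules_gmt),
            netio.read_gene_list(aging_path, name="aging"),
            netio.read_gmt(diseases_gmt),
            labels=netio.read_labels(labels_path) if labels_path else None,
            **params,
        )

    def build_emns(self) -> tuple[list[ExpandedModule], dict[str, int]]:
        """Filter, optionally de-redundify, expand and deduplicate modules."""
        p = self.params
        counts = {"input_modules": len(self.module_sets)}
        sets = modmod.filter_gene_sets(
            self.module_sets, p["min_module_size"], p["max_module_size"]
        )
        counts["size_filtered"] = len(sets)
        if p["redundancy_threshold"] is not None:
            sets = modmod.remove_redundant_sets(sets, p["redundancy_threshold"])
        counts["after_redundancy"] = len(sets)
        solver = RWRSolver(self.network, p["restart"])
        rwr_params = RWRParams(restart=p["restart"], tolerance=p["tolerance"])
        emns = []
        for s in sets:
            emn = modmod.expand_module(
                self.network, s, fold=p["expansion_fold"], cap=p["cap"],
                params=rwr_params, solver=solver,
            )
            if emn is not None:
                emns.append(emn)
        counts["expanded"] = len(emns)
        emns = modmod.dedupe_modules(emns)
        counts["unique_emns"] = len(emns)
        return emns, counts

    def fit(self, seed: int = 0) -> "GeroNetResults":
        """Run the full pipeline; ``seed`` drives every permutation draw and
        makes the run bit-reproducible."""
        p = self.params
        t0 = time.monotonic()
        emns, counts = self.build_emns()
        logger.info("modules: %s", counts)

        pairs = modmod.applicable_pairs(emns, self.aging, self.diseases, p["min_mapped_genes"])
        counts["applicable_pairs"] = len(pairs)
        logger.info("%d applicable (disease, eMN) pairs", len(pairs))

        # one child seed per pair, in deterministic pair order
        ss = np.random.SeedSequence(seed)
        children = ss.spawn(len(pairs))
        engines: dict[str, PairEngine] = {}
        results: list[significance.SignificanceResult] = []
        for (disease, emn), child in zip(pairs, children):
            engine = engines.get(emn.name)
            if engine is None:
                engine = engines[emn.name] = PairEngine(emn, p["restart"])
            res = significance.permutation_null(
                emn,
                self.aging,
                disease,
                beta=p["beta"],
                n_perm=p["n_perm"],
                rng=np.random.default_rng(child),
                restart=p["restart"],
                p_mode=p["p_mode"],
                engine=engine,
            )
            res.seed = seed
            results.append(res)

        if results:
            if p["fdr_family"] == "pooled":
                fdrs = significance.adjust_fdr([r.p for r in results])
                for r, f in zip(results, fdrs):
                    r.fdr = float(f)
            else:
                by_disease: dict[str, list[significance.SignificanceResult]] = {}
                for r in results:
                    by_disease.setdefault(r.disease, []).append(r)
                for rs in by_disease.values():
                    fdrs = significance.adjust_fdr([r.p for r in rs])
                    for r, f in zip(rs, fdrs):
                        r.fdr = float(f)

        by_disease = {}
        for r in results:
            by_disease.setdefault(r.disease, []).append(r)
        scores = [significance.disease_score(rs) for rs in by_disease.values()]
        ranking = significance.rank_diseases(scores)
        logger.info("fit finished in %.1f s", time.monotonic() - t0)
        return GeroNetResults(
            model=self,
            emns=emns,
            pair_results=results,
            ranking=ranking,
            counts=counts,
            seed=seed,
        )


@dataclass
class GeroNetResults:
    """Fitted pipeline results: per-pair significance, per-disease ranking,
    stage counts and (with labels) ARD-recovery AUROC."""

    model: GeroNet
    emns: list[ExpandedModule]
    pair_results: list[significance.SignificanceResult]
    ranking: pd.DataFrame
    counts: dict[str, int]
    seed: int
    _pairs_frame: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def pairs(self) -> pd.DataFrame:
        if self._pairs_frame is None:
            self._pairs_frame = pd.DataFrame(
                {
                    "disease": [r.disease for r in self.pair_results],
                    "emn": [r.emn for r in self.pair_results],
                    "es_beta": [r.observed_es for r in self.pair_results],
                    "es1": [r.es1 for r in self.pair_results],
                    "es2": [r.es2 for r in self.pair_results],
                    "z": [r.z for r in self.pair_results],
                    "p": [r.p for r in self.pair_results],
                    "fdr": [r.fdr for r in self.pair_results],
                    "n_aging_mapped": [r.n_aging_mapped for r in self.pair_results],
                    "n_disease_mapped": [r.n_disease_mapped for r in self.pair_results],
                    "n_overlap": [r.n_overlap for r in self.pair_results],
                }
            )
        return self._pairs_frame

    def disease_scores(self) -> dict[str, float]:
        return dict(zip(self.ranking["disease"], self.ranking["geo_mean_fdr"]))

    def auroc(self, pessimize_unscored: bool = False) -> float:
        """AUROC of ARD recovery by the geometric-mean ranking.  Labeled
        diseases with no applicable eMN are excluded unless
        ``pessimize_unscored``, which assigns them the worst score."""
        if self.model.labels is None:
            raise ValueError("no labels supplied to the model")
        scores = self.disease_scores()
        if pessimize_unscored:
            worst = max(scores.values(), default=1.0)
            for d in self.model.labels:
                scores.setdefault(d, max(1.0, worst))
        return evaluation.auroc(scores, self.model.labels)

    def n_significant_pairs(self, alpha: float = 0.05) -> int:
        return int((self.pairs["fdr"] <= alpha).sum())

    def common_expanded_genes(self, disease_name: str, emn_name: str) -> GeneSet:
        """Genes shared by the expanded aging and expanded disease gene sets
        of one pair — the natural target set for key connector analysis."""
        emn = next(e for e in self.emns if e.name == emn_name)
        disease = next(d for d in self.model.diseases if d.name == disease_name)
        score = mutual_reachability(
            emn, self.model.aging, disease,
            beta=self.model.params["beta"],
        )
        common = score.expanded_aging_genes.genes & score.expanded_disease_genes.genes
        if not common:
            raise ValueError("expanded aging and disease genes share no gene")
        return GeneSet(f"{disease_name}|{emn_name}|common", common)

    def key_connectors(
        self, disease_name: str, emn_name: str, params: KCAParams = KCAParams()
    ) -> list[KeyConnector]:
        """KCA on the eMN subnetwork for the common expanded genes of one
        significant (disease, eMN) pair."""
        emn = next(e for e in self.emns if e.name == emn_name)
        target = self.common_expanded_genes(disease_name, emn_name)
        return key_connectors(emn.subnetwork, target, params)

    def summary(self) -> str:
        p = self.model.params
        lines = [
            "GeroNet aging-disease connection results",
            "=" * 46,
            f"network: {self.model.network.n} genes, {self.model.network.n_edges} edges",
            f"modules: {self.counts.get('input_modules', 0)} in, "
            f"{self.counts.get('unique_emns', 0)} unique eMNs "
            f"(fold={p['expansion_fold']}, cap={p['cap']})",
            f"pairs: {self.counts.get('applicable_pairs', 0)} applicable, "
            f"{self.n_significant_pairs()} significant at FDR<=0.05",
            f"beta={p['beta']}, restart={p['restart']}, n_perm={p['n_perm']}, "
            f"seed={self.seed}",
            "",
            "disease ranking (geometric-mean adjusted p):",
        ]
        frame = self.ranking.copy()
        if self.model.labels is not None:
            frame["ard"] = [
                int(self.model.labels[d]) if d in self.model.labels else -1
                for d in frame["disease"]
            ]
        lines.append(frame.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
        if self.model.labels is not None:
            try:
                lines.append("")
                lines.append(f"AUROC (ARD recovery): {self.auroc():.3f}")
            except ValueError:
                pass
        return "\n".join(lines)

    def to_files(self, outdir) -> dict[str, str]:
        """Write ranking.tsv, pairs.tsv and emns.gmt (deterministic bytes
        given the fit seed)."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "ranking": outdir / "ranking.tsv",
            "pairs": outdir / "pairs.tsv",
            "emns": outdir / "emns.gmt",
        }
        self.ranking.to_csv(paths["ranking"], sep="\t", index=False, float_format="%.10g")
        self.pairs.to_csv(paths["pairs"], sep="\t", index=False, float_format="%.10g")
        netio.write_gmt(
            [GeneSet(e.name, set(e.member_genes)) for e in self.emns], paths["emns"]
        )
        return {k: str(v) for k, v in paths.items()}
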