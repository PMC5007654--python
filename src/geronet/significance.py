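"""Permutation significance of ES_beta, FDR adjustment, and disease ranking.

The null distribution of ES_beta for a (disease, eMN) pair is built by
permuting the aging genes within the eMN: each replicate draws as many
pseudo-aging genes, uniformly without replacement, from the eMN's member
genes, and recomputes ES_beta.  The disease-seeded walk does not depend on
which genes carry the aging label, so its ranking is computed once and only
re-scored per replicate; the aging-seeded walk is re-run from the pseudo
seeds.  The observed score is converted to a z statistic against the null
mean and standard deviation, with a one-sided upper-tail normal p-value.

Per-disease significance is the geometric mean of BH-adjusted p-values over
the disease's applicable eMNs; a smaller geometric mean means a stronger
aging connection, and diseases are ranked ascending on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .modules import ExpandedModule
from .netio import GeneSet
from .reachability import PairEngine, _es_batch, mutual_reachability

__all__ = [
    "SignificanceResult",
    "DiseaseScore",
    "permutation_null",
    "adjust_fdr",
    "disease_score",
    "rank_diseases",
]

P_FLOOR = 1e-300


@dataclass
class SignificanceResult:
    disease: str
    emn: str
    observed_es: float
    es1: float
    es2: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    n_perm: int
    seed: int
    degenerate: bool = False
    fdr: float = float("nan")
    n_aging_mapped: int = 0
    n_disease_mapped: int = 0
    n_overlap: int = 0


@dataclass
class DiseaseScore:
    disease: str
    geo_mean_fdr: float
    n_emns: int
    rank: int = 0


def permutation_null(
    emn: ExpandedModule,
    aging: GeneSet,
    disease: GeneSet,
    beta: float = 0.1,
    n_perm: int = 100,
    rng: np.random.Generator | int | None = None,
    restart: float = 0.7,
    p_mode: str = "normal",
    engine: PairEngine | None = None,
) -> SignificanceResult:
    """Permutation test of the observed ES_beta for one (disease, eMN) pair.

    ``p_mode="normal"`` gives the one-sided upper-tail p of the z statistic;
    ``"empirical"`` gives ``(1 + #{null >= observed}) / (n_perm + 1)``.
    A degenerate null (sd = 0) sets p to 1 when the observed score does not
    exceed the null mean and to ``1/(n_perm + 1)`` otherwise.
    """
    if p_mode not in ("normal", "empirical"):
        raise ValueError(f"unknown p_mode {p_mode!r}")
    seed_used = rng if isinstance(rng, (int, np.integer)) else -1
    rng = np.random.default_rng(rng)
    if engine is None:
        engine = PairEngine(emn, restart)
    observed = mutual_reachability(emn, aging, disease, beta=beta, engine=engine)

    k = engine.net.n
    n_aging = observed.n_aging_mapped
    disease_idx = engine.indices(disease)
    disease_mask = np.zeros(k, dtype=bool)
    disease_mask[disease_idx] = True
    order_d = engine.ranking(disease_idx)

    # pseudo-aging draws: first n_aging slots of a random permutation per row
    draws = np.argsort(rng.random((n_perm, k)), axis=1)[:, :n_aging]
    pseudo_masks = np.zeros((k, n_perm), dtype=bool)
    pseudo_masks[draws.T, np.arange(n_perm)[None, :].repeat(n_aging, axis=0)] = True

    # ES1 replicates: fixed disease-seeded ranking scored on pseudo-aging hits
    es1_null = _es_batch(np.tile(order_d[:, None], (1, n_perm)), pseudo_masks)
    # ES2 replicates: pseudo-aging-seeded walks scored on disease hits
    probs = engine.propagate_batch(draws)
    orders = engine.rank_batch(probs)
    es2_null = _es_batch(orders, disease_mask)
    null = beta * es1_null + (1.0 - beta) * es2_null

    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    degenerate = null_sd == 0.0
    if degenerate:
        z = 0.0 if observed.es_beta <= null_mean else float("inf")
        p = 1.0 if observed.es_beta <= null_mean else 1.0 / (n_perm + 1)
    else:
        z = (observed.es_beta - null_mean) / null_sd
        if p_mode == "normal":
            p = float(norm.sf(z))
        else:
            p = float((1 + np.sum(null >= observed.es_beta)) / (n_perm + 1))
        p = max(p, P_FLOOR)
    return SignificanceResult(
        disease=disease.name,
        emn=emn.name,
        observed_es=observed.es_beta,
        es1=observed.es1,
        es2=observed.es2,
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        p=p,
        n_perm=n_perm,
        seed=int(seed_used),
        degenerate=degenerate,
        n_aging_mapped=observed.n_aging_mapped,
        n_disease_mapped=observed.n_disease_mapped,
        n_overlap=observed.n_overlap,
    )


def adjust_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def disease_score(results: list[SignificanceResult]) -> DiseaseScore:
    """Geometric mean of the adjusted p-values over a disease's eMNs,
    computed in log space for numerical stability."""
    if not results:
        raise ValueError("need at least one significance result")
    names = {r.disease for r in results}
    if len(names) != 1:
        raise ValueError(f"results mix diseases: {sorted(names)}")
    fdrs = np.array([r.fdr for r in results], dtype=float)
    if np.any(np.isnan(fdrs)) or np.any(fdrs <= 0):
        raise ValueError("all results need a positive adjusted p-value (run adjust_fdr first)")
    geo = float(np.exp(np.mean(np.log(fdrs))))
    return DiseaseScore(disease=results[0].disease, geo_mean_fdr=geo, n_emns=len(results))


def rank_diseases(scores: list[DiseaseScore]) -> pd.DataFrame:
    """Ascending geometric-mean FDR (rank 1 = most age-connected); ties
    broken lexicographically by disease name."""
    ordered = sorted(scores, key=lambda s: (s.geo_mean_fdr, s.disease))
    for i, s in enumerate(ordered, 1):
        s.rank = i
    return pd.DataFrame(
        {
            "disease": [s.disease for s in ordered],
            "geo_mean_fdr": [s.geo_mean_fdr for s in ordered],
            "n_emns": [s.n_emns for s in ordered],
            "rank": [s.rank for s in ordered],
        }
    )
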