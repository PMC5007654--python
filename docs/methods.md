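# Methods

## Model

The package models the association between an anchor gene set ("aging
genes") and many query gene sets ("disease genes") as *mutual network
reachability inside functional subnetworks*, rather than direct overlap.
The underlying assumptions are:

- the reference PPI network is undirected and unweighted once a confidence
  threshold has been applied: `A[i,j] = 1` iff proteins i and j interact,
  zero diagonal, symmetric. Edge scores only gate inclusion; they do not
  weight the walk.
- biological functions are module-local: a connection between aging and a
  disease is interpretable when it occurs inside a functionally coherent
  subnetwork (a GO BP or KEGG pathway mapped to the PPI), and a
  whole-network signal can drown in hub traffic.
- proximity is measured by random walk with restart (RWR): the stationary
  distribution of `P_{t+1} = (1−r)·W·P_t + r·P_0` with column-normalised
  `W` and restart `r` scores every gene's closeness to the seed set.

### Transition matrix and degenerate columns

`W` is column-stochastic except for isolated nodes, whose columns are all
zero. Isolated nodes are retained (stable indexing); walk mass that steps
into them is only replenished by the restart term, so on graphs with
isolated nodes the steady state sums to slightly less than 1. This leakage
is accepted and documented rather than renormalised.

### RWR engines

Two solvers share one definition of the fixed point:

- `rwr_steady_state`: the literal power iteration, stopping when the L1
  difference of successive states drops below the tolerance (default 1e-6;
  the stopping norm is a package decision — the convergence criterion is
  conventionally stated as "difference between two steps" without a norm,
  and L1 is scale-free in n). Maximum 10,000 iterations; non-convergence is
  reported, not raised.
- `RWRSolver` / `rwr_exact`: the closed form
  `P = r·(I − (1−r)·W)^{-1}·P_0`, factorised once per network (dense LU up
  to 2,000 nodes, sparse super-LU beyond). For r > 0 and sub-stochastic W
  the system is always non-singular. The pipeline uses this engine because
  each eMN is solved for hundreds of seed vectors (observed walks plus
  permutation replicates); one factorisation turns each of those into a
  triangular solve. The two engines are cross-checked to 1e-5 (L∞) in the
  test suite; the exact solve is the same fixed point, not an
  approximation.

Rankings sort by descending probability with lexicographic gene-name
tie-breaks; probabilities are quantized at 1e-12 (far below solver
tolerance) so that symmetric nodes tie exactly and the ranking is
deterministic across BLAS implementations.

### Expansion rule

An eMN takes the top `min(cap, N·m, n)` ranked genes, where `m` is the
*mapped* module size (the mapped count, not the annotated count, keeps the
target size attainable), `N` the expansion fold (default 4), cap 500.
Identical member sets are deduplicated before pairing so the geometric
mean never double-counts a subnetwork.

### Reachability score

The running sum walks a ranked eMN gene list with increments `+1/G` on a
hit and `−1/(N−G)` on a miss (G hits among N genes) — the unweighted
Kolmogorov–Smirnov GSEA convention, which guarantees the curve ends at
exactly 0. The enrichment score is the curve's maximum (only positive
enrichment is scored); the peak prefix defines the "expanded" gene sets.
Genes belonging to both the aging and the disease set count as hits in both
directions: shared genes are the strongest evidence of connection. ES_β
weights the disease-seeded direction by β (default 0.1) and the
aging-seeded direction by 1−β; the assignment of β to the disease-seeded
score is a declared convention, configurable, and symmetric at β = 0.5.

### Permutation null

Each replicate draws |mapped aging genes| pseudo-aging genes uniformly
without replacement from the eMN members (including disease genes — the
simplest exchangeable null preserving set size) and recomputes ES_β. The
disease-seeded ranking does not depend on which genes carry the aging
label, so it is computed once and re-scored per replicate; the aging-seeded
walk is re-solved from each pseudo-seed set through the cached
factorisation. With 100 replicates the observed score becomes
`z = (ES_obs − mean)/sd` with a one-sided upper-tail normal p (floored at
1e-300); an empirical mode `(1 + #{null ≥ obs})/(n_perm + 1)` is available
for small-sample robustness. A degenerate null (sd = 0) yields p = 1 when
the observed score does not exceed the null mean, else `1/(n_perm+1)`, with
a flag.

### Multiple testing and ranking

BH adjustment is applied to the pooled family of all applicable
(disease, eMN) pairs per run (configurable to per-disease). A disease's
score is the geometric mean of its adjusted p-values, computed in log
space; diseases are ranked ascending with lexicographic tie-breaks. AUROC
(via the Mann–Whitney identity) treats smaller scores as more ARD-like;
labeled diseases with no applicable eMN are excluded by default, with a
`pessimize_unscored` option assigning them the worst score.

### Key connector analysis

Dynamic neighbourhood search on the undirected network: the candidate pool
is the L-ball (default L = 2) around the target set; for each candidate g
and each layer h ≤ H (default 2), the ball of radius h around g inside the
pool (excluding g; a `shell` option tests exact-distance shells instead) is
tested for target enrichment by a hypergeometric test against the pool
minus g. The per-gene statistic is the minimum p over layers; Bonferroni
multiplies by the number of candidates (the per-gene minimum is the unit
of testing, so layers are not counted separately). Target genes are
eligible candidates — a hub inside the target set is still a connector.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `restart` r | 0.7 | probability of teleporting back to seeds each step |
| `tolerance` | 1e-6 | L1 convergence threshold of the power iteration |
| `expansion_fold` N | 4 | eMN size multiplier over mapped module size |
| `cap` | 500 | hard eMN size ceiling |
| `min/max_module_size` | 30 / 500 | module collection filter (inclusive) |
| `min_mapped_genes` | 5 | aging and disease genes required per pair |
| `beta` | 0.1 | weight of the disease-seeded direction in ES_β |
| `n_perm` | 100 | permutation replicates per pair |
| `redundancy_threshold` | off | greedy Jaccard de-redundancy of modules (0.8 typical) |
| KCA `L`, `H`, `alpha` | 2, 2, 0.05 | radius, layers, Bonferroni threshold |

## Synthetic benchmark

The generator emulates the five required inputs without any download. A
Barabási–Albert graph (attachment 3) supplies the heavy-tailed degree
structure RWR exploits; modules are connected BFS neighbourhoods around
random anchors, sized 30–40 so none fall to the size filter; aging genes
concentrate in two aging-heavy modules; each ARD draws `overlap_fraction`
of its genes from the aging set, `connection_strength` of the remainder
from 1-hop neighbours of aging genes inside the aging-heavy modules, and
the rest uniformly; non-ARD gene sets are uniform draws. At
`connection_strength = 0, overlap_fraction = 0` ARD and non-ARD sets are
exchangeable — the calibration null.

Default sizes: 500 nodes, 15 modules, aging set 30, 20 diseases (10 ARDs)
of 20–30 genes, `connection_strength = 0.8`, `overlap_fraction = 0.2`. The
500-node size keeps expanded modules (~120–160 genes) genuinely smaller
than the reference network, so the modularized/whole-network comparison is
meaningful; the problem sizes throughout the tests and the acceptance
script (5 benchmark draws, 2 null draws of ~250 pairs each, 10 seeds × 3
strengths for the monotonicity check, 20 connector fixtures) are the
package's scaled study conditions.

What the generator does **not** emulate: GO DAG semantics and term
redundancy structure, identifier noise and mapping failures, edge
confidence heterogeneity, degree-biased gene-set ascertainment, and
literature-derived label noise. Passing benchmarks therefore demonstrate
that the machinery recovers a planted topological signal and stays
calibrated under an exchangeable null — not that real GenAge/STRING/GWAS
snapshots would reproduce any particular published ranking.

The key-connector fixture plants an articulation gene joining two sparse
ring-with-chords clusters ("aging" and "disease"), with pendant background
genes diluting ordinary members' neighbourhoods; the planted gene is the
only candidate whose layered neighbourhood is enriched for both clusters.

## Numerical and design choices

- Ranking tie-breaks are lexicographic everywhere (gene names, disease
  names), making every output deterministic for a fixed seed; the fit seed
  spawns one child seed per (disease, eMN) pair in a stable order, so runs
  are bit-reproducible end to end.
- The redundancy pass over module collections is greedy in descending size
  order (ties by name): a set survives if its Jaccard with every kept set
  is strictly below the threshold.
- Fisher tests for module overlap are one-sided (enrichment), computed as
  exact hypergeometric upper tails; the module-overlap permutation
  reshuffles gene labels across modules holding sizes fixed and compares
  the observed count of significant overlaps to a normal null.
- Disease-category merging support is average-linkage hierarchical
  clustering on 1 − Jaccard distances; the clustering only *suggests*
  merges.
- Errors are raised early on degenerate inputs: empty gene sets, running
  sums with zero or all hits, single-class labels for AUROC, conflicting
  disease labels, unmappable seed sets.

## Limitations

- The normal approximation to the 100-replicate permutation null is
  slightly anti-conservative for a max-statistic like ES (the null is
  right-skewed); calibration tests bound the nominal 5% rate at ≤ 10%, and
  the empirical p mode is available where exactness matters.
- Whole-network and modularized variants converge in behaviour as module
  size approaches network size; on networks only a few times larger than
  the expansion cap, the comparison between them is uninformative.
- Isolated-node mass leakage means steady states are compared only within
  a fixed network, never across networks with different isolated-node
  counts.
- The KCA Bonferroni counts candidates, not candidate × layer tests;
  with H > 2 this is mildly anti-conservative.
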