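import itertools

import numpy as np
import pytest
from scipy.stats import hypergeom

from conftest import random_network
from geronet.evaluation import (
    auroc,
    cooccurrence_jaccard,
    direct_overlap_scores,
    fisher_enrichment_p,
    jaccard_overlap,
    merge_categories,
    module_overlap_test,
    overlap_count_permutation,
    whole_network_score,
)
from geronet.netio import GeneSet, LabelTable


def auroc_enumeration_oracle(scores, labels):
    """Mann-Whitney pairwise enumeration: P(pos scored below neg) + ties/2,
    with 'below' meaning more ARD-like (smaller score)."""
    pos = [scores[d] for d in scores if labels[d]]
    neg = [scores[d] for d in scores if not labels[d]]
    total = 0.0
    for sp, sn in itertools.product(pos, neg):
        total += 1.0 if sp < sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        scores = {"a": 0.01, "b": 0.02, "c": 0.8, "d": 0.9}
        labels = LabelTable({"a": True, "b": True, "c": False, "d": False})
        assert auroc(scores, labels) == 1.0

    def test_all_ties_is_half(self):
        scores = {d: 0.5 for d in "abcd"}
        labels = LabelTable({"a": True, "b": False, "c": True, "d": False})
        assert auroc(scores, labels) == 0.5

    def test_hand_example(self):
        scores = dict(zip("abcd", [0.01, 0.02, 0.3, 0.4]))
        labels = LabelTable(dict(zip("abcd", [True, False, True, False])))
        assert auroc(scores, labels) == pytest.approx(0.75)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="single-class"):
            auroc({"a": 0.1, "b": 0.2}, LabelTable({"a": True, "b": True}))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        names = [f"d{i}" for i in range(n)]
        scores = {d: float(rng.choice([0.1, 0.2, 0.5, rng.random()])) for d in names}
        flags = rng.random(n) < 0.5
        if flags.all() or not flags.any():
            flags[0] = not flags[0]
        labels = LabelTable(dict(zip(names, map(bool, flags))))
        assert auroc(scores, labels) == pytest.approx(
            auroc_enumeration_oracle(scores, labels), abs=1e-10
        )


class TestJaccard:
    def test_identical(self):
        s = GeneSet("s", {"a", "b", "c"})
        assert jaccard_overlap(s, s) == 1.0

    def test_disjoint(self):
        assert jaccard_overlap(GeneSet("a", {"x"}), GeneSet("b", {"y"})) == 0.0

    def test_half(self):
        a, b = GeneSet("a", {"a", "b", "c"}), GeneSet("b", {"b", "c", "d"})
        assert jaccard_overlap(a, b) == 0.5

    def test_cooccurrence_on_identifier_sets(self):
        assert cooccurrence_jaccard({1, 2, 3}, {2, 3, 4}) == 0.5
        assert cooccurrence_jaccard({1}, {2}) == 0.0
        with pytest.raises(ValueError):
            cooccurrence_jaccard(set(), set())

    def test_direct_overlap_scores_orientation(self):
        aging = GeneSet("aging", {"a", "b", "c"})
        near = GeneSet("near", {"a", "b", "x"})
        far = GeneSet("far", {"y", "z"})
        scores = direct_overlap_scores(aging, [near, far])
        assert scores["near"] < scores["far"]  # smaller = more age-connected


class TestFisherHypergeom:
    def test_exhaustive_tail_oracle(self):
        # overlap 5, a-only 5, b-only 5, background 100
        p = fisher_enrichment_p(5, 10, 10, 100)
        oracle = sum(hypergeom.pmf(k, 100, 10, 10) for k in range(5, 11))
        assert p == pytest.approx(oracle, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_tables_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        bg = int(rng.integers(20, 200))
        na = int(rng.integers(1, bg // 2))
        nb = int(rng.integers(1, bg // 2))
        ov = int(rng.integers(0, min(na, nb) + 1))
        oracle = sum(hypergeom.pmf(k, bg, na, nb) for k in range(ov, min(na, nb) + 1))
        assert fisher_enrichment_p(ov, na, nb, bg) == pytest.approx(oracle, abs=1e-10)

    def test_module_larger_than_background_errors(self):
        with pytest.raises(ValueError):
            fisher_enrichment_p(1, 50, 10, 20)

    def test_disjoint_small_modules_near_one(self):
        assert fisher_enrichment_p(0, 5, 5, 1000) == pytest.approx(1.0)


class TestMergeCategories:
    def test_identical_sets_one_cluster(self):
        a, b = GeneSet("A", {"x", "y"}), GeneSet("B", {"x", "y"})
        assert merge_categories([a, b], cut_height=0.1) == [["A", "B"]]

    def test_disjoint_sets_singletons(self):
        sets = [GeneSet(n, {n + "1", n + "2"}) for n in "ABC"]
        clusters = merge_categories(sets, cut_height=0.5)
        assert sorted(clusters) == [["A"], ["B"], ["C"]]

    def test_near_duplicates_cluster_apart_from_outsider(self):
        a = GeneSet("A", {f"g{i}" for i in range(10)})
        b = GeneSet("B", {f"g{i}" for i in range(9)} | {"h"})
        c = GeneSet("C", {"u", "v", "w"})
        clusters = merge_categories([a, b, c], cut_height=0.5)
        assert ["A", "B"] in clusters and ["C"] in clusters


class TestModuleOverlap:
    def test_matrix_shape_and_self_overlap(self):
        mods = [GeneSet(f"m{i}", {f"g{i}_{j}" for j in range(10)}) for i in range(3)]
        om = module_overlap_test(mods, mods, background_n=100)
        assert om.pvalues.shape == (3, 3)
        # diagonal (self-overlap) minimal in each row
        assert np.all(np.argmin(om.pvalues, axis=1) == np.arange(3))
        assert np.all(om.fdr >= om.pvalues - 1e-12)

    def test_overlap_count_permutation_behaviour(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(100)]
        c2 = [GeneSet(f"z{i}", set(genes[20 * i : 20 * (i + 1)])) for i in range(5)]
        c1 = [GeneSet(f"t{i}", set(genes[20 * i : 20 * i + 15])) for i in range(5)]
        null_mean, null_sd, p, observed = overlap_count_permutation(
            c1, c2, [m.name for m in c2], background_n=100, n_perm=50, rng_seed=1
        )
        assert observed == 5  # every c1 module nails its c2 counterpart
        assert p < 0.5
        again = overlap_count_permutation(
            c1, c2, [m.name for m in c2], background_n=100, n_perm=50, rng_seed=1
        )
        assert (null_mean, null_sd, p, observed) == again

    def test_too_few_replicates_rejected(self):
        c = [GeneSet("a", {"x", "y"})]
        with pytest.raises(ValueError):
            overlap_count_permutation(c, c, ["a"], 10, n_perm=1)


class TestWholeNetworkBaseline:
    def test_identical_sets_score_high(self):
        rng = np.random.default_rng(1)
        net = random_network(rng, 40, p=0.25)
        genes = GeneSet("s", set(net.nodes[:8]))
        score = whole_network_score(net, genes, GeneSet("d", set(genes.genes)), beta=0.5)
        assert score.es_beta > 0.9

    def test_requires_five_mapped_genes(self):
        rng = np.random.default_rng(2)
        net = random_network(rng, 30, p=0.3)
        small = GeneSet("s", set(net.nodes[:3]))
        big = GeneSet("b", set(net.nodes[5:15]))
        with pytest.raises(ValueError, match=">=5"):
            whole_network_score(net, small, big)
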