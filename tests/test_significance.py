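import numpy as np
import pytest

from conftest import random_network
from geronet.modules import ExpandedModule
from geronet.netio import GeneSet
from geronet.significance import (
    DiseaseScore,
    SignificanceResult,
    adjust_fdr,
    disease_score,
    permutation_null,
    rank_diseases,
)


def bh_reference(p):
    """Independent step-up BH oracle, straight from the definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running_min = min(running_min, p[idx] * m / rank)
        adj[idx] = running_min
    return np.minimum(adj, 1.0)


class TestAdjustFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_fdr([0.03]), [0.03])

    def test_hand_example(self):
        np.testing.assert_allclose(adjust_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        np.testing.assert_allclose(adjust_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_empty(self):
        assert adjust_fdr([]).size == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reference_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 40)))
        np.testing.assert_allclose(adjust_fdr(p), bh_reference(p), atol=1e-10)

    def test_fdr_at_least_p(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(1e-6, 1.0, size=25)
        assert np.all(adjust_fdr(p) >= p - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.0, 0.5])


def _fixture_pair(seed=0, n=60, p=0.15, n_aging=8, n_disease=8):
    rng = np.random.default_rng(seed)
    net = random_network(rng, n, p=p)
    emn = ExpandedModule("e", GeneSet("e", set(net.nodes)), list(net.nodes), net, 1, n)
    picks = rng.choice(net.nodes, size=n_aging + n_disease, replace=False)
    aging = GeneSet("aging", set(picks[:n_aging]))
    disease = GeneSet("d", set(picks[n_aging:]))
    return emn, aging, disease


class TestPermutationNull:
    def test_fields_and_ranges(self):
        emn, aging, disease = _fixture_pair()
        res = permutation_null(emn, aging, disease, n_perm=50, rng=1)
        assert res.n_perm == 50
        assert 0 < res.p <= 1
        if not res.degenerate:
            assert res.z == pytest.approx(
                (res.observed_es - res.null_mean) / res.null_sd
            )

    def test_reproducible_given_rng_seed(self):
        emn, aging, disease = _fixture_pair(seed=2)
        a = permutation_null(emn, aging, disease, n_perm=40, rng=7)
        b = permutation_null(emn, aging, disease, n_perm=40, rng=7)
        assert (a.null_mean, a.null_sd, a.z, a.p) == (b.null_mean, b.null_sd, b.z, b.p)

    def test_empirical_mode_bounds(self):
        emn, aging, disease = _fixture_pair(seed=3)
        res = permutation_null(emn, aging, disease, n_perm=30, rng=5, p_mode="empirical")
        assert 1 / 31 <= res.p <= 1.0

    def test_observed_at_null_mean_gives_half(self):
        # z = 0 maps to p = 0.5 under the one-sided normal tail
        from scipy.stats import norm

        assert norm.sf(0.0) == 0.5

    def test_permuted_set_equal_to_true_set_reproduces_observed(self):
        """A replicate whose pseudo-aging draw equals the real aging set must
        produce the observed score: check by running the 'null' with the
        aging genes as the only possible draw (eMN members = aging+disease)."""
        from geronet.reachability import mutual_reachability

        rng = np.random.default_rng(4)
        net = random_network(rng, 16, p=0.5)
        emn = ExpandedModule("e", GeneSet("e", set(net.nodes)), list(net.nodes),
                             net, 1, 16)
        aging = GeneSet("aging", set(net.nodes))  # every member is aging
        disease = GeneSet("d", set(net.nodes[:6]))
        with pytest.raises(ValueError):
            # all-members hit set is degenerate for the running sum
            mutual_reachability(emn, aging, disease)


class TestDiseaseScore:
    def _res(self, disease, fdr):
        return SignificanceResult(
            disease=disease, emn="e", observed_es=0.5, es1=0.5, es2=0.5,
            null_mean=0.0, null_sd=1.0, z=1.0, p=0.1, n_perm=10, seed=0, fdr=fdr,
        )

    def test_single_emn(self):
        assert disease_score([self._res("A", 0.2)]).geo_mean_fdr == pytest.approx(0.2)

    def test_geometric_mean_in_log_space(self):
        score = disease_score([self._res("A", 1e-2), self._res("A", 1e-4)])
        assert score.geo_mean_fdr == pytest.approx(1e-3)

    def test_equal_fdrs_identity(self):
        score = disease_score([self._res("A", 0.3)] * 4)
        assert score.geo_mean_fdr == pytest.approx(0.3)

    def test_bounded_by_min_max_and_permutation_invariant(self):
        rng = np.random.default_rng(6)
        fdrs = rng.uniform(1e-5, 1.0, size=9)
        results = [self._res("A", f) for f in fdrs]
        g1 = disease_score(results).geo_mean_fdr
        g2 = disease_score(results[::-1]).geo_mean_fdr
        assert g1 == pytest.approx(g2)
        assert fdrs.min() <= g1 <= fdrs.max()

    def test_mixed_diseases_rejected(self):
        with pytest.raises(ValueError, match="mix"):
            disease_score([self._res("A", 0.1), self._res("B", 0.1)])

    def test_missing_fdr_rejected(self):
        bad = self._res("A", float("nan"))
        with pytest.raises(ValueError):
            disease_score([bad])


class TestRankDiseases:
    def test_ascending_order(self):
        frame = rank_diseases(
            [DiseaseScore("B", 0.1, 3), DiseaseScore("A", 0.001, 3)]
        )
        assert list(frame["disease"]) == ["A", "B"]
        assert list(frame["rank"]) == [1, 2]

    def test_ties_lexicographic(self):
        frame = rank_diseases(
            [DiseaseScore("Z", 0.5, 1), DiseaseScore("A", 0.5, 1)]
        )
        assert list(frame["disease"]) == ["A", "Z"]

    def test_single_disease(self):
        frame = rank_diseases([DiseaseScore("only", 0.9, 2)])
        assert list(frame["rank"]) == [1]
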