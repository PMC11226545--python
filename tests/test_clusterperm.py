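"""Edge statistics, SCC clustering and the permutation test."""

import numpy as np
import pytest

from oscflux import (build_clusters, contrast_topography, edge_tstats,
                     permutation_test, strongly_connected_partition)
from oscflux.clusterperm import EdgeStats


def brute_force_scc(n_nodes: int, edges: list) -> list:
    """Oracle: SCCs via boolean transitive closure (mutual reachability)."""
    reach = np.eye(n_nodes, dtype=bool)
    for (u, v) in edges:
        reach[u, v] = True
    for _ in range(n_nodes):
        reach = reach | (reach @ reach)
    mutual = reach & reach.T
    comps, seen = [], set()
    for i in range(n_nodes):
        if i not in seen:
            comp = set(np.flatnonzero(mutual[i]).tolist())
            comps.append(comp)
            seen |= comp
    return comps


def antisym_from_edges(n_ch, edge_values):
    m = np.zeros((n_ch, n_ch))
    for (i, j), v in edge_values.items():
        m[i, j] = v
        m[j, i] = -v
    return m


class TestEdgeTstats:
    def test_identical_conditions_give_zero_t(self):
        rng = np.random.default_rng(0)
        psis = [antisym_from_edges(4, {(0, 1): rng.normal(), (2, 3): rng.normal()})
                for _ in range(6)]
        stats = edge_tstats(psis, psis)
        np.testing.assert_allclose(np.nan_to_num(stats.t), 0.0)

    def test_t_formula_exact(self):
        # differences on edge (0,1) with sample mean 1 and sample SD 1 -> t = 5
        n = 25
        rng = np.random.default_rng(3)
        d = rng.standard_normal(n)
        d = (d - d.mean()) / d.std(ddof=1) + 1.0
        psiA = [np.zeros((3, 3)) for _ in range(n)]
        psiB = [antisym_from_edges(3, {(0, 1): d[k]}) for k in range(n)]
        stats = edge_tstats(psiA, psiB)
        assert stats.t[0, 1] == pytest.approx(5.0, abs=1e-9)
        assert stats.t[1, 0] == pytest.approx(-5.0, abs=1e-9)

    def test_antisymmetric_inputs_give_antisymmetric_t(self):
        rng = np.random.default_rng(1)
        psiA = [antisym_from_edges(4, {(i, j): rng.normal()
                                       for i in range(4) for j in range(i + 1, 4)})
                for _ in range(8)]
        psiB = [antisym_from_edges(4, {(i, j): rng.normal()
                                       for i in range(4) for j in range(i + 1, 4)})
                for _ in range(8)]
        stats = edge_tstats(psiA, psiB)
        np.testing.assert_allclose(stats.t, -stats.t.T, atol=1e-10)

    def test_pairwise_missing_exclusion(self):
        psiA = [antisym_from_edges(3, {(0, 1): 0.0}) for _ in range(6)]
        psiB = [antisym_from_edges(3, {(0, 1): v}) for v in [1., 2., 3., 1., 2., 3.]]
        psiB[0][0, 1] = np.nan
        stats = edge_tstats(psiA, psiB)
        assert stats.n[0, 1] == 5

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError, match="3 participants"):
            edge_tstats([np.zeros((2, 2))] * 2, [np.zeros((2, 2))] * 2)


class TestBuildClusters:
    def _stats(self, n_ch, sig_edges, t=4.0):
        tmat = np.zeros((n_ch, n_ch))
        pmat = np.ones((n_ch, n_ch))
        for (i, j) in sig_edges:
            tmat[i, j], tmat[j, i] = t, -t
            pmat[i, j] = pmat[j, i] = 0.01
        return EdgeStats(t=tmat, p=pmat, n=np.full((n_ch, n_ch), 10))

    def test_no_surviving_edges_gives_no_clusters(self):
        stats = self._stats(4, [])
        assert build_clusters(stats, np.zeros((4, 4)), np.zeros((4, 4))) == []

    def test_cycle_forms_single_cluster(self):
        # B-condition mean PSI orients edges into the cycle 0->1->2->0
        mean_b = antisym_from_edges(3, {(0, 1): 1.0, (1, 2): 1.0, (2, 0): 1.0})
        stats = self._stats(3, [(0, 1), (1, 2), (0, 2)])
        clusters = build_clusters(stats, np.zeros((3, 3)), mean_b)
        assert len(clusters) == 1
        assert sorted(clusters[0].edges) == [(0, 1), (1, 2), (2, 0)]
        assert clusters[0].condition_membership == "B"
        assert brute_force_scc(3, clusters[0].edges) == [{0, 1, 2}]

    def test_disjoint_edges_form_singleton_clusters(self):
        mean_b = antisym_from_edges(4, {(0, 1): 1.0, (2, 3): 1.0})
        stats = self._stats(4, [(0, 1), (2, 3)])
        clusters = build_clusters(stats, np.zeros((4, 4)), mean_b)
        assert len(clusters) == 2
        assert all(len(c.edges) == 1 for c in clusters)

    def test_membership_assigned_by_larger_absolute_psi(self):
        mean_a = antisym_from_edges(3, {(0, 1): -2.0})
        mean_b = antisym_from_edges(3, {(0, 1): 0.5})
        stats = self._stats(3, [(0, 1)])
        clusters = build_clusters(stats, mean_a, mean_b)
        assert clusters[0].condition_membership == "A"
        # oriented by A's mean sign: psi[0,1] < 0 so channel 1 drives
        assert clusters[0].edges == [(1, 0)]

    @pytest.mark.parametrize("seed", range(100))
    def test_scc_partition_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        density = rng.uniform(0.1, 0.7)
        edges = [(i, j) for i in range(n) for j in range(n)
                 if i != j and rng.random() < density]
        ours = strongly_connected_partition(n, edges, mode="strong")
        oracle = brute_force_scc(n, edges)
        assert sorted(map(sorted, ours)) == sorted(map(sorted, oracle))

    def test_weak_mode_joins_chains(self):
        # 0->1, 1->2: weakly one component, strongly three singletons
        mean_b = antisym_from_edges(3, {(0, 1): 1.0, (1, 2): 1.0})
        stats = self._stats(3, [(0, 1), (1, 2)])
        strong = build_clusters(stats, np.zeros((3, 3)), mean_b, scc_mode="strong")
        weak = build_clusters(stats, np.zeros((3, 3)), mean_b, scc_mode="weak")
        assert len(strong) == 2
        assert len(weak) == 1
        assert weak[0].cluster_stat == pytest.approx(8.0)


class TestPermutationTest:
    def _paired_data(self, n=12, n_ch=4, effect=0.0, seed=0):
        rng = np.random.default_rng(seed)
        psiA, psiB = [], []
        for _ in range(n):
            a = antisym_from_edges(n_ch, {(i, j): rng.normal()
                                          for i in range(n_ch)
                                          for j in range(i + 1, n_ch)})
            b = antisym_from_edges(n_ch, {(i, j): rng.normal()
                                          for i in range(n_ch)
                                          for j in range(i + 1, n_ch)})
            b[0, 1] += effect
            b[1, 0] -= effect
            psiA.append(a)
            psiB.append(b)
        return psiA, psiB

    def test_deterministic_given_seed(self):
        psiA, psiB = self._paired_data(effect=2.0)
        r1 = permutation_test(psiA, psiB, n_perm=200, seed=7)
        r2 = permutation_test(psiA, psiB, n_perm=200, seed=7)
        np.testing.assert_array_equal(r1.null_distribution, r2.null_distribution)
        assert [c.p_value for c in r1.clusters] == [c.p_value for c in r2.clusters]

    def test_planted_edge_detected(self):
        psiA, psiB = self._paired_data(effect=3.0, seed=2)
        res = permutation_test(psiA, psiB, n_perm=300, seed=1)
        assert len(res.significant_clusters) >= 1
        top = max(res.significant_clusters, key=lambda c: abs(c.cluster_stat))
        assert (0, 1) in top.edges
        assert top.condition_membership == "B"
        assert top.p_value < 0.05

    def test_global_label_swap_negates_t_and_swaps_membership(self):
        psiA, psiB = self._paired_data(effect=2.0, seed=5)
        s1 = edge_tstats(psiA, psiB)
        s2 = edge_tstats(psiB, psiA)
        np.testing.assert_allclose(s1.t, -s2.t, atol=1e-10)
        mean_a = np.nanmean(psiA, axis=0)
        mean_b = np.nanmean(psiB, axis=0)
        c1 = build_clusters(s1, mean_a, mean_b)
        c2 = build_clusters(s2, mean_b, mean_a)
        m1 = {tuple(sorted(c.edges)): c.condition_membership for c in c1}
        m2 = {tuple(sorted(c.edges)): c.condition_membership for c in c2}
        swap = {"A": "B", "B": "A"}
        assert m2 == {k: swap[v] for k, v in m1.items()}

    def test_insufficient_sample_rejected(self):
        psiA, psiB = self._paired_data(n=1)
        with pytest.raises(ValueError, match="insufficient sample"):
            permutation_test(psiA, psiB, n_perm=100, seed=0)

    def test_tiny_n_perm_rejected_small_warned(self, caplog):
        psiA, psiB = self._paired_data()
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(psiA, psiB, n_perm=5, seed=0)
        with caplog.at_level("WARNING", logger="oscflux.clusterperm"):
            permutation_test(psiA, psiB, n_perm=50, seed=0)
        assert any("small" in r.message for r in caplog.records)

    def test_pvalues_use_add_one_estimator(self):
        psiA, psiB = self._paired_data(effect=5.0, seed=3)
        res = permutation_test(psiA, psiB, n_perm=100, seed=0)
        for c in res.clusters:
            assert 1 / 101 <= c.p_value <= 1.0


class TestContrastTopography:
    def test_identical_conditions_give_zero_map(self):
        m = np.random.default_rng(0).normal(size=(8, 4))
        rows = contrast_topography(m, m, channels=list("abcd"))
        assert all(r["t"] == pytest.approx(0.0) for r in rows)

    def test_shifted_channel_dominates_map(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(15, 4))
        b = a + rng.normal(0, 0.3, size=(15, 4))
        b[:, 2] += 2.0
        rows = contrast_topography(a, b, channels=list("abcd"))
        assert max(rows, key=lambda r: abs(r["t"]))["channel"] == "c"

    def test_missing_values_excluded_pairwise(self):
        a = np.ones((5, 2))
        b = np.tile([[2.0, 3.0]], (5, 1)) + np.arange(5)[:, None] * 0.1
        b[0, 1] = np.nan
        rows = contrast_topography(a, b)
        assert rows[0]["n"] == 5
        assert rows[1]["n"] == 4
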