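"""Cluster permutation machinery: t maps, connected components,
exact enumeration, and cross-checks against independent oracles."""

import itertools

import numpy as np
import pytest

from oscishift import (
    NeighborGraph,
    StatsParams,
    cluster_permutation_test,
    find_clusters,
    paired_t_map,
)


def _chain_graph(names):
    edges = {frozenset((a, b)) for a, b in zip(names[:-1], names[1:])}
    return NeighborGraph(channel_ids=list(names), edges=edges)


class TestPairedTMap:
    def test_null_and_antisymmetry(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((5, 2, 4))
        m0 = paired_t_map(A, A)
        assert np.all(m0.t == 0)
        B = rng.standard_normal((5, 2, 4))
        assert np.allclose(paired_t_map(A, B).t, -paired_t_map(B, A).t)

    def test_closed_form_value(self):
        # subject differences {1, 2, 3}: t = 2 / (1/sqrt(3)) = 3.464...
        A = np.asarray([1.0, 2.0, 3.0])[:, None, None]
        B = np.zeros_like(A)
        m = paired_t_map(A, B)
        assert m.t[0, 0] == pytest.approx(2 * np.sqrt(3), rel=1e-12)
        assert m.df == 2

    def test_zero_variance_counted_degenerate(self):
        A = np.ones((4, 1, 2))
        B = np.zeros_like(A)
        m = paired_t_map(A, B)
        assert np.all(m.t == 0)
        assert m.n_degenerate == 2


class TestFindClusters:
    def test_contiguous_run(self):
        t = np.asarray([[0.0, 3.0, 3.0, 3.0, 0.0]])
        m = paired_t_map(np.zeros((2, 1, 5)), np.zeros((2, 1, 5)))
        m.t = t
        cl = find_clusters(m, threshold_t=2.0)
        assert len(cl) == 1
        assert len(cl[0].members) == 3
        assert cl[0].mass == pytest.approx(9.0)

    def test_non_neighbor_channels_disconnect(self):
        m = paired_t_map(np.zeros((2, 2, 3)), np.zeros((2, 2, 3)))
        m.t = np.asarray([[0.0, 3.0, 0.0], [0.0, 3.0, 0.0]])
        g = NeighborGraph(channel_ids=["ch00", "ch01"], edges=set())
        assert len(find_clusters(m, 2.0, g)) == 2
        g2 = NeighborGraph(channel_ids=["ch00", "ch01"],
                           edges={frozenset(("ch00", "ch01"))})
        assert len(find_clusters(m, 2.0, g2)) == 1

    def test_broken_chain_path(self):
        # a~b, b~c; suprathreshold at (a, bin5) and (c, bin5); b below threshold
        m = paired_t_map(np.zeros((2, 3, 8)), np.zeros((2, 3, 8)))
        tmap = np.zeros((3, 8))
        tmap[0, 5] = 4.0
        tmap[2, 5] = 4.0
        m.t = tmap
        m.channel_ids = ["a", "b", "c"]
        g = _chain_graph(["a", "b", "c"])
        assert len(find_clusters(m, 2.0, g)) == 2

    def test_against_brute_force_components(self):
        # exhaustive reference on random small maps
        rng = np.random.default_rng(5)
        names = ["a", "b", "c", "d"]
        g = _chain_graph(names)
        for _ in range(20):
            tmap = rng.standard_normal((4, 6)) * 2
            m = paired_t_map(np.zeros((2, 4, 6)), np.zeros((2, 4, 6)))
            m.t = tmap
            m.channel_ids = names
            got = find_clusters(m, 2.0, g, tail="two")
            # brute force: union-find over all suprathreshold pairs
            nodes = [(c, b) for c in range(4) for b in range(6) if abs(tmap[c, b]) > 2.0]
            parent = {n: n for n in nodes}

            def find(n):
                while parent[n] != n:
                    parent[n] = parent[parent[n]]
                    n = parent[n]
                return n

            for (c1, b1), (c2, b2) in itertools.combinations(nodes, 2):
                same_sign = np.sign(tmap[c1, b1]) == np.sign(tmap[c2, b2])
                adjacent = (c1 == c2 and abs(b1 - b2) == 1) or (
                    b1 == b2 and abs(c1 - c2) == 1)  # chain graph adjacency
                if same_sign and adjacent:
                    parent[find((c1, b1))] = find((c2, b2))
            expected = {}
            for n in nodes:
                expected.setdefault(find(n), set()).add(n)
            got_sets = {frozenset(c.members) for c in got}
            assert got_sets == {frozenset(v) for v in expected.values()}


class TestClusterPermutationTest:
    def test_identical_data_reports_no_clusters(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((6, 2, 5))
        res = cluster_permutation_test(A, A, params=StatsParams(n_permutations=200))
        assert res.clusters == []

    def test_exact_p_values_are_dyadic(self):
        rng = np.random.default_rng(2)
        n = 6
        A = rng.standard_normal((n, 1, 4)) + 1.5
        B = rng.standard_normal((n, 1, 4))
        res = cluster_permutation_test(A, B, params=StatsParams(n_permutations=200))
        assert res.exact and res.n_permutations == 2 ** n
        for c in res.clusters:
            assert (c.p * 2 ** n) == pytest.approx(round(c.p * 2 ** n))
            assert c.p >= 1.0 / 2 ** n

    def test_monte_carlo_agrees_with_enumeration(self):
        rng = np.random.default_rng(3)
        n = 5
        A = rng.standard_normal((n, 2, 4)) + 1.2
        B = rng.standard_normal((n, 2, 4))
        g = NeighborGraph(channel_ids=["ch00", "ch01"],
                          edges={frozenset(("ch00", "ch01"))})
        exact = cluster_permutation_test(
            A, B, graph=g, params=StatsParams(n_permutations=100, method="exact"))
        mc = cluster_permutation_test(
            A, B, graph=g,
            params=StatsParams(n_permutations=10000, method="montecarlo", seed=4))
        assert exact.exact and not mc.exact
        for ce, cm in zip(exact.clusters, mc.clusters):
            assert ce.members == cm.members
            assert cm.p == pytest.approx(ce.p, abs=0.02)

    def test_global_sign_flip_invariance(self):
        rng = np.random.default_rng(6)
        A = rng.standard_normal((6, 1, 6)) + 0.8
        B = rng.standard_normal((6, 1, 6))
        r1 = cluster_permutation_test(A, B, params=StatsParams(n_permutations=200))
        r2 = cluster_permutation_test(B, A, params=StatsParams(n_permutations=200))
        p1 = sorted(c.p for c in r1.clusters)
        p2 = sorted(c.p for c in r2.clusters)
        assert p1 == pytest.approx(p2)

    def test_positive_offset_does_not_shrink_positive_mass(self):
        rng = np.random.default_rng(7)
        A = rng.standard_normal((8, 1, 6)) + 1.0
        B = rng.standard_normal((8, 1, 6))
        base = cluster_permutation_test(A, B, params=StatsParams(n_permutations=128))
        shifted = cluster_permutation_test(A + 0.5, B, params=StatsParams(n_permutations=128))
        pos_base = max((c.mass for c in base.clusters if c.sign == 1), default=0.0)
        pos_shift = max((c.mass for c in shifted.clusters if c.sign == 1), default=0.0)
        assert pos_shift >= pos_base

    def test_p_never_zero(self):
        # enormous effect: p bounded below by the +1 / identity correction
        A = np.full((8, 1, 4), 10.0) + np.random.default_rng(8).normal(0, 0.01, (8, 1, 4))
        B = np.zeros_like(A)
        res = cluster_permutation_test(A, B, params=StatsParams(n_permutations=5000))
        assert res.clusters[0].p > 0

    def test_mne_cross_check(self):
        # independent implementation of the same 1-sample cluster test
        mne_stats = pytest.importorskip("mne.stats")
        rng = np.random.default_rng(9)
        n = 8
        d = rng.standard_normal((n, 12)) + 0.9  # (subjects, times), one channel
        from scipy import stats as sps

        thr = sps.t.ppf(1 - 0.05 / 2, df=n - 1)
        t_obs, clusters, pvals, _ = mne_stats.permutation_cluster_1samp_test(
            d, threshold=thr, n_permutations="all", tail=0, adjacency=None,
            seed=0, out_type="mask", verbose="error")
        mine = cluster_permutation_test(
            d[:, None, :], np.zeros_like(d)[:, None, :],
            params=StatsParams(n_permutations=2 ** n))
        mne_best = min(pvals)
        assert mine.clusters[0].p == pytest.approx(mne_best, abs=0.02)
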