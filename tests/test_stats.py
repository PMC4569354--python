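import itertools

import numpy as np
import pytest

from megnet import (PermutationScheme, demographics, fdr_regional,
                    mann_whitney, nbs, node_cluster_permutation,
                    power_cluster_test, spearman_corr)
from megnet.stats import _label_matrix, positions_to_adjacency


class TestMannWhitney:
    def test_exact_small_sample(self):
        """A={1,2}, B={3,4}: U=0, exact two-sided p = 2/6."""
        res = mann_whitney([1, 2], [3, 4])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_groups_p_one(self):
        res = mann_whitney([2, 2, 2], [2, 2])
        assert res.p_value == 1.0

    def test_matches_permutation_oracle(self, rng):
        a = rng.normal(0.8, 1, 13)
        b = rng.normal(0.0, 1, 19)
        res = mann_whitney(a, b)
        # Monte-Carlo permutation oracle on the rank-sum statistic
        pooled = np.concatenate([a, b])
        ranks = np.argsort(np.argsort(pooled)) + 1.0
        obs = ranks[:13].sum()
        n_mc = 100_000
        perm_rng = np.random.default_rng(0)
        stats = np.empty(n_mc)
        for i in range(n_mc):
            perm_rng.shuffle(ranks)
            stats[i] = ranks[:13].sum()
        mu = stats.mean()
        p_mc = np.mean(np.abs(stats - mu) >= abs(obs - mu) - 1e-9)
        assert res.p_value == pytest.approx(p_mc, abs=0.01)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([1], [2, 3])


class TestSpearman:
    def test_monotone_is_one(self):
        res = spearman_corr([1, 2, 3, 4, 5], [10, 20, 25, 30, 100])
        assert res.statistic == pytest.approx(1.0)

    def test_antimonotone_is_minus_one(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        res = spearman_corr(x, -x)
        assert res.statistic == pytest.approx(-1.0)

    def test_matches_permutation_oracle_n10(self, rng):
        x = rng.standard_normal(10)
        y = 0.5 * x + rng.standard_normal(10)
        res = spearman_corr(x, y)
        from scipy.stats import rankdata
        rx, ry = rankdata(x), rankdata(y)
        rxc = rx - rx.mean()
        n_mc = 100_000
        perm_rng = np.random.default_rng(1)
        rhos = np.empty(n_mc)
        denom = np.sqrt((rxc**2).sum())
        for i in range(n_mc):
            perm_rng.shuffle(ry)
            ryc = ry - ry.mean()
            rhos[i] = (ryc @ rxc) / (denom * np.sqrt((ryc**2).sum()))
        p_mc = np.mean(np.abs(rhos) >= abs(res.statistic) - 1e-12)
        assert res.p_value == pytest.approx(p_mc, abs=0.01)

    def test_exact_small_n_superuniform(self):
        # n=5 -> exact permutation p; p can never be below 2/5! for |rho|
        res = spearman_corr([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert res.p_value >= 2 / 120 - 1e-12

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_corr([1, 1, 1, 1], [1, 2, 3, 4])


class TestDemographics:
    def test_study_sex_table(self):
        """9/13 vs 11/19 female: chi-square p = 0.515 to 3 decimals."""
        res = demographics([[9, 4], [11, 8]])
        assert round(res["sex"].p_value, 3) == 0.515

    def test_identical_proportions_zero_statistic(self):
        res = demographics([[10, 20], [5, 10]])
        assert res["sex"].statistic == pytest.approx(0.0, abs=1e-12)
        assert res["sex"].p_value == pytest.approx(1.0)

    def test_chi_square_matches_hand_expansion(self):
        table = np.array([[7.0, 5.0], [12.0, 9.0]])
        res = demographics(table)
        rowsum = table.sum(axis=1, keepdims=True)
        colsum = table.sum(axis=0, keepdims=True)
        expected = rowsum * colsum / table.sum()
        chi2 = ((table - expected) ** 2 / expected).sum()
        assert res["sex"].statistic == pytest.approx(chi2, rel=1e-12)

    def test_age_from_raw_values(self, rng):
        a = rng.normal(38.6, 15.8, 13)
        b = rng.normal(38.5, 13.5, 19)
        res = demographics([[9, 4], [11, 8]], ages_a=a, ages_b=b)
        assert 0 <= res["age"].p_value <= 1

    def test_age_from_summary_stats(self):
        res = demographics([[9, 4], [11, 8]],
                           age_summary=((38.6, 15.8, 13), (38.5, 13.5, 19)))
        assert res["age"].p_value > 0.9  # means nearly identical

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            demographics([[0, 0], [5, 3]])


class TestFdrRegional:
    @staticmethod
    def oracle_bh(pvals, q):
        """Independent sort-and-scan step-up rule."""
        m = len(pvals)
        order = sorted(range(m), key=lambda i: pvals[i])
        passed = [False] * m
        kmax = 0
        for rank, idx in enumerate(order, start=1):
            if pvals[idx] <= rank * q / m:
                kmax = rank
        for rank, idx in enumerate(order, start=1):
            if rank <= kmax:
                passed[idx] = True
        return passed

    def test_textbook_step_up(self):
        # regions engineered to give p ~ {tiny, tiny, big}: just check
        # agreement with the oracle on the raw p-values
        rng = np.random.default_rng(0)
        A = rng.normal(0, 1, (13, 6))
        B = rng.normal(0, 1, (19, 6))
        A[:, :2] += 2.0
        out = fdr_regional(A, B, q=0.05)
        raw = [r.p_value for r in out]
        expect = self.oracle_bh(raw, 0.05)
        assert [r.extra["significant"] for r in out] == expect

    def test_oracle_agreement_many_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            A = rng.normal(0, 1, (8, 10))
            B = rng.normal(rng.uniform(0, 1.5), 1, (9, 10))
            out = fdr_regional(A, B, q=0.05)
            raw = [r.p_value for r in out]
            assert [r.extra["significant"] for r in out] == self.oracle_bh(raw, 0.05)

    def test_all_p_one_none_pass(self):
        A = np.ones((5, 3))
        B = np.ones((5, 3))
        out = fdr_regional(A, B, q=0.05)
        assert not any(r.extra["significant"] for r in out)


class TestLabelMatrix:
    def test_full_enumeration_small_groups(self):
        G = _label_matrix(2, 3, 100, seed=0)
        assert G.shape == (10, 5)  # C(5,2) distinct assignments
        assert G[0, :2].all() and not G[0, 2:].any()  # identity first
        assert len({tuple(row) for row in G}) == 10

    def test_monte_carlo_includes_identity(self):
        G = _label_matrix(13, 19, 500, seed=1)
        assert G.shape == (500, 32)
        assert G[0, :13].all() and not G[0, 13:].any()
        assert np.all(G.sum(axis=1) == 13)


class TestClusterPermutation:
    def _line_positions(self, n, spacing=1.0):
        pos = np.zeros((n, 3))
        pos[:, 0] = np.arange(n) * spacing
        return pos

    def test_distant_supra_nodes_stay_separate(self, rng):
        """Two effects farther apart than the adjacency radius never merge."""
        n_nodes = 9
        pos = self._line_positions(n_nodes)
        A = rng.normal(0, 0.1, (13, n_nodes))
        B = rng.normal(0, 0.1, (19, n_nodes))
        A[:, 0] += 5.0
        A[:, 6] += 5.0
        clusters = node_cluster_permutation(
            A, B, pos, spacing=1.0,
            scheme=PermutationScheme(n_permutations=200, threshold=2.0,
                                     alpha=0.01, seed=0))
        positive = [c for c in clusters if c.sign > 0]
        member_sets = [set(c.members) for c in positive]
        assert {0} in member_sets and {6} in member_sets
        assert not any({0, 6} <= s for s in member_sets)

    def test_lower_threshold_clusters_are_supersets(self, rng):
        n_nodes = 12
        pos = self._line_positions(n_nodes)
        A = rng.normal(0, 1, (13, n_nodes)) + np.linspace(0, 1.5, n_nodes)
        B = rng.normal(0, 1, (19, n_nodes))
        nodes_19 = set()
        nodes_20 = set()
        for thr, acc in ((1.9, nodes_19), (2.0, nodes_20)):
            cl = power_cluster_test(
                A, B, pos, spacing=1.0,
                scheme=PermutationScheme(n_permutations=100, threshold=thr,
                                         alpha=0.05, seed=0))
            for c in cl:
                acc |= set(c.members)
        assert nodes_20 <= nodes_19

    def test_no_supra_nodes_empty_result(self, rng):
        pos = self._line_positions(5)
        A = np.tile(np.arange(5.0), (13, 1)) + rng.normal(0, 1e-6, (13, 5))
        B = np.tile(np.arange(5.0), (19, 1)) + rng.normal(0, 1e-6, (19, 5))
        clusters = node_cluster_permutation(
            A, B, pos, spacing=1.0,
            scheme=PermutationScheme(n_permutations=100, threshold=50.0,
                                     alpha=0.01, seed=0))
        assert clusters == []

    def test_reproducible_with_seed(self, rng):
        pos = self._line_positions(8)
        A = rng.normal(0, 1, (10, 8)) + 0.8
        B = rng.normal(0, 1, (12, 8))
        scheme = PermutationScheme(n_permutations=300, threshold=2.0,
                                   alpha=0.05, seed=99)
        c1 = node_cluster_permutation(A, B, pos, 1.0, scheme)
        c2 = node_cluster_permutation(A, B, pos, 1.0, scheme)
        assert [(c.members, c.p_value) for c in c1] == \
               [(c.members, c.p_value) for c in c2]

    def test_planted_blob_recovered(self, rng):
        """Contiguous 10-node strength increase at d~2 is detected."""
        n_nodes = 40
        pos = self._line_positions(n_nodes)
        blob = set(range(10, 20))
        hits = 0
        for rep in range(10):
            rep_rng = np.random.default_rng(1000 + rep)
            A = rep_rng.normal(0, 1, (13, n_nodes))
            B = rep_rng.normal(0, 1, (19, n_nodes))
            A[:, list(blob)] += 2.0
            clusters = node_cluster_permutation(
                A, B, pos, spacing=1.0,
                scheme=PermutationScheme(n_permutations=500, threshold=2.0,
                                         alpha=0.01, seed=rep))
            detected = set()
            for c in clusters:
                if c.p_value < 0.01 and c.sign > 0:
                    detected |= set(c.members)
            if len(detected & blob) / len(blob) >= 0.5:
                hits += 1
        assert hits >= 8


class TestNbs:
    def _nets(self, rng, n_subj, n_reg, boost_edges=(), boost=0.0):
        nets = rng.uniform(0.05, 0.25, (n_subj, n_reg, n_reg))
        nets = (nets + nets.transpose(0, 2, 1)) / 2
        for i, j in boost_edges:
            nets[:, i, j] += boost
            nets[:, j, i] += boost
        for k in range(n_subj):
            np.fill_diagonal(nets[k], 0)
        return np.clip(nets, 0, 1)

    def test_disjoint_supra_edges_two_components(self, rng):
        A = self._nets(rng, 13, 6, boost_edges=[(0, 1), (3, 4)], boost=0.5)
        B = self._nets(rng, 19, 6)
        comps = nbs(A, B, PermutationScheme(n_permutations=200, threshold=3.5,
                                            alpha=0.05, seed=0))
        positive = [c for c in comps if c.sign > 0]
        edge_sets = [set(c.members) for c in positive]
        assert {(0, 1)} in edge_sets and {(3, 4)} in edge_sets
        assert all(len(s) == 1 or not ({(0, 1), (3, 4)} <= s) for s in edge_sets)

    def test_connected_supra_edges_one_component(self, rng):
        A = self._nets(rng, 13, 6, boost_edges=[(0, 1), (1, 2)], boost=0.5)
        B = self._nets(rng, 19, 6)
        comps = nbs(A, B, PermutationScheme(n_permutations=200, threshold=3.5,
                                            alpha=0.05, seed=0))
        big = max((c for c in comps if c.sign > 0), key=lambda c: c.statistic)
        assert set(big.members) >= {(0, 1), (1, 2)}

    def test_extent_vs_sum_statistics(self, rng):
        A = self._nets(rng, 10, 5, boost_edges=[(0, 1)], boost=0.6)
        B = self._nets(rng, 12, 5)
        scheme = PermutationScheme(n_permutations=100, threshold=3.5,
                                   alpha=0.05, seed=0)
        ext = nbs(A, B, scheme, statistic="extent")
        sm = nbs(A, B, scheme, statistic="sum")
        assert ext and float(ext[0].statistic).is_integer()
        assert sm and sm[0].statistic > 3.5  # summed |t| exceeds threshold

    def test_components_match_networkx(self, rng):
        """Supra-threshold edge grouping against an independent graph library."""
        import networkx as nx

        from megnet.stats import _pooled_t
        A = self._nets(rng, 13, 8, boost_edges=[(0, 1), (1, 2), (4, 5)],
                       boost=0.4)
        B = self._nets(rng, 19, 8)
        iu = np.triu_indices(8, 1)
        X = np.vstack([A[:, iu[0], iu[1]], B[:, iu[0], iu[1]]])
        t_obs = _pooled_t(X, _label_matrix(13, 19, 100, 0)[:1], 13, 19)[0]
        supra = [(int(iu[0][e]), int(iu[1][e]))
                 for e in np.flatnonzero(t_obs > 3.5)]
        g = nx.Graph(supra)
        nx_comps = {frozenset((min(u, v), max(u, v)) for u, v in g.subgraph(c).edges)
                    for c in nx.connected_components(g)}
        comps = nbs(A, B, PermutationScheme(n_permutations=100, threshold=3.5,
                                            alpha=0.05, seed=0))
        ours = {frozenset(c.members) for c in comps if c.sign > 0}
        assert ours == nx_comps

    def test_too_few_regions_rejected(self, rng):
        A = self._nets(rng, 5, 2)
        with pytest.raises(ValueError):
            nbs(A, A)


def test_adjacency_radius_rule():
    pos = np.array([[0.0, 0, 0], [0.01, 0, 0], [0.025, 0, 0]])
    adj = positions_to_adjacency(pos, spacing=0.01)
    assert adj[0, 1] and not adj[0, 2] and not adj[1, 2]
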