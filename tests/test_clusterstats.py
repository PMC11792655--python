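"""Cluster permutation machinery, coupling statistics, moderation."""

import numpy as np
import pytest
from scipy import stats

from priomatch.clusterstats import (Adjacency, cluster_permutation,
                                    group_moderation, make_adjacency,
                                    pointwise_correlation,
                                    window_correlation, _cluster_masses)


@pytest.fixture(scope="module")
def adj():
    return make_adjacency()


class TestAdjacency:
    def test_symmetric_irreflexive_connected(self, adj):
        for i, nb in enumerate(adj.neighbors):
            assert i not in nb
            assert len(nb) >= 1
            for j in nb:
                assert i in adj.neighbors[j]

    def test_median_degree_near_four(self, adj):
        assert 3 <= adj.median_degree <= 6


def _chain_adjacency(n):
    nb = []
    for i in range(n):
        cur = [j for j in (i - 1, i + 1) if 0 <= j < n]
        nb.append(np.array(cur, dtype=np.int64))
    return Adjacency(ch_names=[f"c{i}" for i in range(n)], neighbors=nb)


def _brute_force_clusters(tmap, tcrit, neighbors):
    """Reference connected components via plain BFS over supra-threshold
    points (same-sign connectivity, chain channels x consecutive time)."""
    n_ch, n_t = tmap.shape
    seen = np.zeros_like(tmap, dtype=bool)
    masses = []
    for c in range(n_ch):
        for t in range(n_t):
            if seen[c, t] or not abs(tmap[c, t]) > tcrit:
                continue
            sign = np.sign(tmap[c, t])
            stack, mass = [(c, t)], 0.0
            seen[c, t] = True
            while stack:
                cc, tt = stack.pop()
                mass += tmap[cc, tt]
                cand = [(cc, tt - 1), (cc, tt + 1)] + \
                    [(int(x), tt) for x in neighbors[cc]]
                for (c2, t2) in cand:
                    if 0 <= t2 < n_t and not seen[c2, t2] and \
                            np.sign(tmap[c2, t2]) == sign and \
                            abs(tmap[c2, t2]) > tcrit:
                        seen[c2, t2] = True
                        stack.append((c2, t2))
            masses.append(mass)
    return sorted(masses)


class TestClusteringKernel:
    def test_agrees_with_brute_force_on_toy_grids(self):
        """Exhaustive check against a BFS oracle on random 5x5 maps."""
        adj5 = _chain_adjacency(5)
        idx, ptr = adj5.as_flat()
        rng = np.random.default_rng(0)
        for _ in range(50):
            tmap = rng.normal(0, 2, (5, 5))
            labels = np.zeros((5, 5), dtype=np.int64)
            masses, mx = _cluster_masses(tmap, 1.5, idx, ptr, labels)
            ref = _brute_force_clusters(tmap, 1.5, adj5.neighbors)
            assert sorted(masses) == pytest.approx(ref)
            if len(ref):
                assert mx == pytest.approx(max(abs(m) for m in ref))
            # partition: every supra-threshold point in exactly one cluster
            supra = np.abs(tmap) > 1.5
            assert np.array_equal(labels > 0, supra)

    def test_nan_points_never_join_clusters(self):
        adj5 = _chain_adjacency(3)
        idx, ptr = adj5.as_flat()
        tmap = np.full((3, 3), 5.0)
        tmap[1, 1] = np.nan
        labels = np.zeros((3, 3), dtype=np.int64)
        _cluster_masses(tmap, 2.0, idx, ptr, labels)
        assert labels[1, 1] == 0


class TestClusterPermutation:
    def test_planted_effect_detected(self, adj):
        rng = np.random.default_rng(1)
        diffs = rng.normal(0, 1, (30, 30, 120))
        diffs[:, 3:8, 40:80] += 1.0
        res = cluster_permutation(diffs, adj, n_perm=500, seed=2)
        assert res.clusters[0]["p_perm"] < 0.05
        assert res.clusters[0]["sign"] == 1

    def test_sign_flip_antisymmetry(self, adj):
        rng = np.random.default_rng(3)
        diffs = rng.normal(0, 1, (12, 30, 60))
        diffs[:, 2:6, 10:40] += 0.8
        a = cluster_permutation(diffs, adj, n_perm=300, seed=4)
        b = cluster_permutation(-diffs, adj, n_perm=300, seed=4)
        assert b.clusters[0]["mass"] == pytest.approx(-a.clusters[0]["mass"])
        assert b.clusters[0]["p_perm"] == a.clusters[0]["p_perm"]
        assert b.clusters[0]["sign"] == -a.clusters[0]["sign"]

    def test_p_values_bounded_by_add_one_rule(self, adj):
        rng = np.random.default_rng(5)
        diffs = rng.normal(0, 1, (10, 30, 40))
        res = cluster_permutation(diffs, adj, n_perm=200, seed=6)
        for c in res.clusters:
            assert 1 / 201 <= c["p_perm"] <= 1.0

    def test_subject_order_invariance(self, adj):
        rng = np.random.default_rng(7)
        diffs = rng.normal(0, 1, (10, 30, 40))
        a = cluster_permutation(diffs, adj, n_perm=100, seed=8)
        b = cluster_permutation(diffs[::-1].copy(), adj, n_perm=100, seed=8)
        assert [c["mass"] for c in a.clusters] == \
            pytest.approx([c["mass"] for c in b.clusters])

    def test_degenerate_variance_points_excluded(self, adj):
        rng = np.random.default_rng(9)
        diffs = rng.normal(0, 1, (8, 30, 40))
        diffs[:, 0, 0] = 3.0  # zero variance across subjects
        res = cluster_permutation(diffs, adj, n_perm=100, seed=10)
        assert np.isnan(res.tmap[0, 0])
        assert res.labels[0, 0] == 0

    def test_single_subject_raises(self, adj):
        with pytest.raises(ValueError):
            cluster_permutation(np.zeros((1, 30, 10)), adj)


class TestPointwiseCorrelation:
    def test_planted_coupling_run_covers_the_window(self):
        rng = np.random.default_rng(11)
        times = np.arange(0, 800.0)
        tpl = ((times >= 542) & (times <= 668)).astype(float)
        scalars = rng.normal(0, 1, 40)
        signals = scalars[:, None] * tpl[None, :] + \
            rng.normal(0, 0.6, (40, len(times)))
        out = pointwise_correlation(signals, scalars, times, run_length=100)
        assert out["runs"], "no qualifying run found"
        run = out["runs"][0]
        assert run["t_start_ms"] <= 560 and run["t_end_ms"] >= 650

    def test_run_shorter_than_criterion_not_reported(self):
        rng = np.random.default_rng(12)
        times = np.arange(0, 300.0)
        scalars = rng.normal(0, 1, 30)
        signals = scalars[:, None] * np.ones((1, len(times))) * 5
        out = pointwise_correlation(signals + rng.normal(0, .1, signals.shape),
                                    scalars, times, run_length=len(times) + 1)
        assert out["runs"] == []
        assert (out["p"] < 0.05).all()

    def test_independent_scalar_rarely_yields_runs(self):
        rng = np.random.default_rng(13)
        times = np.arange(0, 400.0)
        hits = 0
        for _ in range(20):
            signals = rng.normal(0, 1, (25, len(times)))
            scalars = rng.normal(0, 1, 25)
            out = pointwise_correlation(signals, scalars, times,
                                        run_length=100)
            hits += bool(out["runs"])
        assert hits <= 2

    def test_constant_scalar_raises(self):
        with pytest.raises(ValueError):
            pointwise_correlation(np.random.default_rng(0).normal(size=(6, 10)),
                                  np.ones(6), np.arange(10.0))


class TestWindowCorrelation:
    def test_monotone_pairs_hit_the_bounds(self):
        x = np.arange(10.0)
        assert window_correlation(x, -x)["rho"] == pytest.approx(-1.0)
        assert window_correlation(x, x ** 3)["rho"] == pytest.approx(1.0)

    def test_null_correlations_stay_small(self):
        rng = np.random.default_rng(14)
        bad = sum(abs(window_correlation(rng.normal(size=200),
                                         rng.normal(size=200))["rho"]) >= 0.2
                  for _ in range(40))
        assert bad <= 2

    def test_ties_only_raises(self):
        with pytest.raises(ValueError):
            window_correlation(np.ones(8), np.arange(8.0))


class TestGroupModeration:
    def test_identical_slopes_give_null_interaction(self):
        rng = np.random.default_rng(15)
        x = rng.normal(0, 1, 200)
        y = 0.5 * x + rng.normal(0, 0.5, 200)
        g = ["FP"] * 100 + ["SP"] * 100
        out = group_moderation(x, y, g)
        assert out["p"] > 0.01

    def test_opposite_slopes_without_noise_are_decisive(self):
        x = np.linspace(-1, 1, 100)
        y = np.concatenate([x[:50], -x[50:]])
        g = ["FP"] * 50 + ["SP"] * 50
        out = group_moderation(x, y, g)
        assert out["p"] < 1e-12
        assert out["slopes"]["FP"] == pytest.approx(1.0)
        assert out["slopes"]["SP"] == pytest.approx(-1.0)

    def test_singular_design_raises(self):
        with pytest.raises(ValueError):
            group_moderation(np.zeros(12), np.arange(12.0),
                             ["FP"] * 6 + ["SP"] * 6)

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            group_moderation(np.arange(6.0), np.arange(6.0), ["FP"] * 6)
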