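"""Neighbor alteration, epicenters, spin and rewired null models."""

import numpy as np
import pytest
from scipy import stats

from eibm import netmap, synthcohort


def brute_force_neighbor_alteration(d, sc, fc=None):
    """Literal double-loop of the neighbor-alteration definition."""
    n = len(d)
    out = np.full(n, np.nan)
    for i in range(n):
        acc, deg = 0.0, 0
        for j in range(n):
            if j == i or sc[i, j] == 0:
                continue
            w = d[j] * sc[i, j]
            if fc is not None:
                w *= fc[i, j]
            acc += w
            deg += 1
        if deg:
            out[i] = acc / deg
    return out


class TestNeighborAlteration:
    def test_three_node_hand_example(self):
        sc = np.array([[0, 2, 4], [2, 0, 0], [4, 0, 0]], float)
        d = np.array([0.0, 0.5, 1.0])
        out = netmap.neighbor_alteration(d, sc)
        assert out[0] == pytest.approx((0.5 * 2 + 1.0 * 4) / 2)

    def test_three_node_fc_weighted(self):
        sc = np.array([[0, 2, 4], [2, 0, 0], [4, 0, 0]], float)
        fc = np.array([[1, 0.5, 0.25], [0.5, 1, 0], [0.25, 0, 1]])
        d = np.array([0.0, 0.5, 1.0])
        out = netmap.neighbor_alteration(d, sc, fc)
        assert out[0] == pytest.approx((0.5 * 2 * 0.5 + 1.0 * 4 * 0.25) / 2)

    def test_binary_sc_constant_map(self):
        rng = np.random.default_rng(0)
        adj = rng.random((10, 10)) < 0.4
        adj = np.triu(adj, 1)
        sc = (adj | adj.T).astype(float)
        d = np.full(10, 0.7)
        out = netmap.neighbor_alteration(d, sc)
        connected = sc.sum(axis=1) > 0
        np.testing.assert_allclose(out[connected], 0.7)

    @pytest.mark.parametrize("with_fc", [False, True])
    def test_matches_brute_force_on_random_graphs(self, with_fc):
        rng = np.random.default_rng(1)
        for n in (5, 8, 12):
            a = np.triu(rng.random((n, n)) * (rng.random((n, n)) < 0.5), 1)
            sc = a + a.T
            fc = None
            if with_fc:
                f = np.triu(rng.uniform(-1, 1, (n, n)), 1)
                fc = f + f.T + np.eye(n)
            d = rng.standard_normal(n)
            np.testing.assert_allclose(
                netmap.neighbor_alteration(d, sc, fc),
                brute_force_neighbor_alteration(d, sc, fc),
                atol=1e-12,
            )

    def test_all_zero_sc_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            netmap.neighbor_alteration(np.ones(4), np.zeros((4, 4)))


class TestEpicenterLikelihood:
    def test_self_profile_ranks_first(self, conn68, rng):
        k = 7
        d = conn68.sc[k].copy()
        d[k] = d[d > 0].mean()  # fill the excluded self-entry
        res = netmap.epicenter_likelihood(d, conn68.sc)
        assert res["likelihood"][k] == pytest.approx(1.0)
        assert res["rank"][k] == 1

    def test_random_map_no_strong_epicenter(self, conn68):
        rng = np.random.default_rng(3)
        maxes = []
        for _ in range(5):
            res = netmap.epicenter_likelihood(rng.standard_normal(68), conn68.sc)
            maxes.append(np.nanmax(np.abs(res["likelihood"])))
        assert np.mean(maxes) < 0.5

    def test_monotone_transform_invariance(self, conn68, rng):
        d = rng.standard_normal(68)
        a = netmap.epicenter_likelihood(d, conn68.sc)["likelihood"]
        b = netmap.epicenter_likelihood(np.exp(2 * d), conn68.sc)["likelihood"]
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestSpin:
    def test_constant_map_invariant(self, parc68):
        surr = netmap.spin_surrogates(np.full(68, 2.5), parc68, 20, seed=0)
        np.testing.assert_allclose(surr, 2.5)

    def test_hemisphere_values_stay_within_hemisphere(self, parc68, rng):
        m = np.concatenate([np.zeros(34), np.ones(34)])
        surr = netmap.spin_surrogates(m, parc68, 50, seed=1)
        assert (surr[:, :34] == 0).all()
        assert (surr[:, 34:] == 1).all()

    def test_surrogate_values_from_original_multiset(self, parc68, rng):
        m = rng.standard_normal(68)
        surr = netmap.spin_surrogates(m, parc68, 10, seed=2)
        assert np.isin(surr, m).all()

    def test_autocorrelation_preserved(self, parc68):
        """Surrogates keep the spatial autocorrelation of the source map:
        the surrogate-to-original Moran's I ratio, averaged over maps,
        stays within 25% of unity."""
        from scipy.spatial.distance import pdist, squareform

        w = np.exp(-squareform(pdist(parc68.centroids)))
        hemi = np.zeros((68, 68))
        hemi[:34, :34] = hemi[34:, 34:] = 1
        w *= hemi  # smoothness lives within each hemisphere surface
        ratios = []
        for seed in range(10):
            m, _ = synthcohort.make_annotation_maps(parc68, smoothness=10, seed=seed)
            surr = netmap.spin_surrogates(m, parc68, 200, seed=1000 + seed)
            surr_i = np.mean([netmap.morans_i(s, w) for s in surr])
            ratios.append(surr_i / netmap.morans_i(m, w))
        assert abs(np.mean(ratios) - 1) < 0.25

    def test_identical_maps_extreme_p(self, parc68):
        mye, _ = synthcohort.make_annotation_maps(parc68, seed=5)
        res = netmap.spin_pvalue(
            lambda a, b: float(np.corrcoef(a, b)[0, 1]), mye, mye, parc68,
            n=199, seed=6,
        )
        assert res.observed == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_null_distribution_invariants(self, parc68):
        mye, grad = synthcohort.make_annotation_maps(parc68, seed=7)
        res = netmap.spin_pvalue(
            lambda a, b: float(np.corrcoef(a, b)[0, 1]), mye, grad, parc68,
            n=99, seed=8,
        )
        assert 0 < res.p_value <= 1
        assert len(res.surrogates) == 99
        assert np.all(np.abs(res.surrogates) <= 1)


class TestRewire:
    def test_invariants_exact(self, conn68):
        sc, dist = conn68.sc, conn68.dist
        surr = netmap.rewire_preserving_length(sc, dist, seed=0)
        assert np.allclose(surr, surr.T)
        # degree sequence preserved exactly
        np.testing.assert_array_equal(
            (surr > 0).sum(axis=1), (sc > 0).sum(axis=1)
        )
        # edge count preserved
        assert np.count_nonzero(surr) == np.count_nonzero(sc)
        # weight multiset preserved
        iu = np.triu_indices(68, 1)
        np.testing.assert_allclose(
            np.sort(surr[iu][surr[iu] > 0]), np.sort(sc[iu][sc[iu] > 0])
        )
        # network actually changed
        assert not np.allclose(surr, sc)

    def test_rewired_positive_control(self, conn68, parc68):
        """A map diffused along SC neighborhoods is detected against the
        rewired null."""
        rng = np.random.default_rng(9)
        sc = conn68.sc
        w = sc / sc.sum(axis=1, keepdims=True)
        detected = 0
        for seed in range(10):
            d = rng.standard_normal(68)
            for _ in range(4):  # smooth along the graph
                d = 0.5 * d + 0.5 * (w @ d)
            res = netmap.rewired_pvalue(
                netmap.node_neighbor_coupling, d, sc, conn68.dist,
                n_null=99, seed=100 + seed,
            )
            detected += res.p_value < 0.05
        assert detected >= 8

    def test_surrogate_statistics_bounded(self, conn68, rng):
        res = netmap.rewired_pvalue(
            netmap.node_neighbor_coupling, rng.standard_normal(68),
            conn68.sc, conn68.dist, n_null=20, seed=3,
        )
        assert np.isfinite(res.surrogates).all()
        assert (np.abs(res.surrogates) <= 1).all()
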