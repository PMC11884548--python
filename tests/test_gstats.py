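"""Group statistics: normalization, sorting, linear models, summaries."""

import numpy as np
import pytest
from scipy import stats

from eibm import gstats
from eibm.synthcohort import make_geometry


def brute_force_bh(p, alpha=0.05):
    """Step-up BH from the definition, for cross-checking."""
    n = len(p)
    order = np.argsort(p)
    thresh = alpha * np.arange(1, n + 1) / n
    below = np.flatnonzero(p[order] <= thresh)
    k = below.max() + 1 if len(below) else 0
    rej = np.zeros(n, bool)
    rej[order[:k]] = True
    q = np.empty(n)
    q_sorted = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    q[order] = np.minimum(q_sorted, 1)
    return q, rej


class TestZscore:
    def test_controls_self_normalized(self, rng):
        ctrl = rng.standard_normal((10, 6)) * 3 + 5
        pt = rng.standard_normal((8, 6))
        _, ctrl_z = gstats.zscore_to_controls(pt, ctrl)
        np.testing.assert_allclose(ctrl_z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(ctrl_z.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_patient_at_control_mean_is_zero(self, rng):
        ctrl = rng.standard_normal((10, 4))
        pt = np.tile(ctrl.mean(axis=0), (1, 1))
        pt_z, _ = gstats.zscore_to_controls(pt, ctrl)
        np.testing.assert_allclose(pt_z, 0, atol=1e-12)

    def test_shift_invariance(self, rng):
        ctrl = rng.standard_normal((10, 4))
        pt = rng.standard_normal((5, 4))
        a, _ = gstats.zscore_to_controls(pt, ctrl)
        b, _ = gstats.zscore_to_controls(pt + 3.7, ctrl + 3.7)
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_zero_sd_names_region(self, rng):
        ctrl = rng.standard_normal((5, 3))
        ctrl[:, 1] = 2.0
        with pytest.raises(ValueError, match=r"\[1\]"):
            gstats.zscore_to_controls(ctrl, ctrl)


class TestFlipToIpsi:
    def test_left_focus_identity(self, parc16, rng):
        m = rng.standard_normal(16)
        np.testing.assert_array_equal(gstats.flip_to_ipsi(m, "L", parc16), m)

    def test_right_focus_involution(self, parc16, rng):
        m = rng.standard_normal(16)
        twice = gstats.flip_to_ipsi(gstats.flip_to_ipsi(m, "R", parc16), "R", parc16)
        np.testing.assert_array_equal(twice, m)

    def test_right_focus_swaps_hemispheres(self, parc16):
        m = np.concatenate([np.ones(8), np.full(8, 2.0)])
        flipped = gstats.flip_to_ipsi(m, "R", parc16)
        assert (flipped[:8] == 2).all() and (flipped[8:] == 1).all()


class TestCompareRegions:
    def test_cohens_d_zero_for_identical_groups(self, rng):
        # same maps AND same covariates in both groups: the group term
        # cannot explain anything, so adjusted d is exactly zero
        maps = rng.standard_normal((20, 10))
        age = rng.uniform(20, 60, 20)
        sex = rng.choice(["M", "F"], 20)
        comp = gstats.compare_regions(
            maps, maps.copy(), np.tile(age, 2), np.tile(sex, 2)
        )
        np.testing.assert_allclose(comp.cohens_d, 0, atol=1e-10)

    def test_type_one_error_calibrated(self):
        """Label-permuted null: region-wise p < .05 rate in [0.03, 0.07]."""
        rng = np.random.default_rng(123)
        hits, total = 0, 0
        for _ in range(50):
            maps = rng.standard_normal((40, 30))
            age = rng.uniform(20, 60, 40)
            sex = rng.choice(["M", "F"], 40)
            comp = gstats.compare_regions(maps[:20], maps[20:], age, sex)
            hits += (comp.p < 0.05).sum()
            total += 30
        assert 0.03 <= hits / total <= 0.07

    def test_pure_age_effect_does_not_inflate_group_term(self):
        rng = np.random.default_rng(7)
        hits, total = 0, 0
        for _ in range(50):
            age = rng.uniform(20, 60, 40)
            maps = 0.05 * age[:, None] + rng.standard_normal((40, 20))
            sex = rng.choice(["M", "F"], 40)
            comp = gstats.compare_regions(maps[:20], maps[20:], age, sex)
            hits += (comp.p < 0.05).sum()
            total += 20
        assert 0.03 <= hits / total <= 0.07

    def test_direction_negative_when_patients_lower(self, rng):
        ctrl = rng.standard_normal((20, 5)) + 1.0
        pt = rng.standard_normal((20, 5))
        age = rng.uniform(20, 60, 40)
        sex = rng.choice(["M", "F"], 40)
        comp = gstats.compare_regions(ctrl, pt, age, sex)
        assert (comp.cohens_d < 0).all()

    def test_rank_deficient_design_rejected(self, rng):
        maps = rng.standard_normal((12, 4))
        age = np.full(12, 30.0)
        sex = np.array(["M"] * 12)  # constant sex + constant age -> collinear
        with pytest.raises(ValueError, match="collinear"):
            gstats.compare_regions(maps[:6], maps[6:], age, sex)


class TestSummaryStats:
    @pytest.mark.parametrize(
        "args,expected_t",
        [
            ((34.25, 3.98, 40, 35.80, 11.04, 40), 0.84),
            ((31.83, 11.35, 30, 30.87, 11.46, 30), 0.33),
        ],
    )
    def test_summary_ttest_known_values(self, args, expected_t):
        t, p = gstats.summary_ttest(*args)
        assert abs(t) == pytest.approx(expected_t, abs=0.005)

    def test_equal_summaries_zero(self):
        t, p = gstats.summary_ttest(5, 1, 10, 5, 1, 10)
        assert t == 0 and p == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table,expected",
        [([[19, 21], [17, 23]], 0.20), ([[11, 19], [10, 20]], 0.07),
         ([[10, 10], [10, 10]], 0.0)],
    )
    def test_chisq_known_values(self, table, expected):
        chi2, _ = gstats.chisq_2x2(table)
        assert chi2 == pytest.approx(expected, abs=0.005)

    def test_chisq_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            gstats.chisq_2x2([[0, 0], [5, 5]])


class TestPartialCorr:
    def test_no_covariates_equals_pearson(self, rng):
        x, y = rng.standard_normal((2, 50))
        r, _, p = gstats.partial_corr(x, y)
        rp, pp = stats.pearsonr(x, y)
        assert r == pytest.approx(rp)
        assert p == pytest.approx(pp, abs=1e-10)

    def test_identical_variables(self, rng):
        x = rng.standard_normal(30)
        z = rng.standard_normal(30)
        r, _, _ = gstats.partial_corr(x, x.copy(), z)
        assert r == pytest.approx(1.0)

    def test_conditional_independence(self):
        rng = np.random.default_rng(0)
        small = 0
        for _ in range(100):
            z = rng.standard_normal(500)
            x = z + rng.standard_normal(500)
            y = -z + rng.standard_normal(500)
            r, _, _ = gstats.partial_corr(x, y, z)
            small += abs(r) < 0.1
        assert small >= 95


class TestNetworkMeans:
    def test_constant_map(self, rng):
        comm = np.array([0, 0, 1, 1, 2, 2])
        ctrl = np.full((8, 6), 3.0) + rng.standard_normal((8, 6)) * 1e-9
        pt = np.full((8, 6), 3.0) + rng.standard_normal((8, 6)) * 1e-9
        res = gstats.network_means(ctrl, pt, comm)
        np.testing.assert_allclose(res["mean_control"], 3.0, atol=1e-6)

    def test_single_community_whole_map(self, rng):
        ctrl = rng.standard_normal((10, 5))
        pt = rng.standard_normal((10, 5)) + 1
        res = gstats.network_means(ctrl, pt, np.zeros(5, int))
        t_direct, _ = stats.ttest_ind(pt.mean(axis=1), ctrl.mean(axis=1))
        assert res["t"][0] == pytest.approx(t_direct)

    def test_null_cohort_rarely_significant(self):
        rng = np.random.default_rng(5)
        comm = np.repeat(np.arange(4), 5)
        none_sig = 0
        for _ in range(50):
            ctrl = rng.standard_normal((15, 20))
            pt = rng.standard_normal((15, 20))
            res = gstats.network_means(ctrl, pt, comm)
            none_sig += not res["significant"].any()
        assert none_sig >= 45


class TestPC1:
    def test_rank_one_full_variance(self, rng):
        u = rng.standard_normal(10)
        v = rng.uniform(0.5, 2, 4)
        scores, ve = gstats.pc1_scores(np.outer(u, v))
        assert ve == pytest.approx(1.0)

    def test_isotropic_variance_fraction(self):
        rng = np.random.default_rng(1)
        _, ve = gstats.pc1_scores(rng.standard_normal((4000, 5)))
        assert ve == pytest.approx(1 / 5, abs=0.02)

    def test_sign_convention(self, rng):
        base = rng.standard_normal((30, 1))
        m = base + 0.3 * rng.standard_normal((30, 4))
        scores, _ = gstats.pc1_scores(m)
        assert np.corrcoef(scores, m.mean(axis=1))[0, 1] > 0

    def test_zero_variance_column_rejected(self, rng):
        m = rng.standard_normal((10, 3))
        m[:, 2] = 1.0
        with pytest.raises(ValueError, match=r"\[2\]"):
            gstats.pc1_scores(m)


class TestBH:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        from statsmodels.stats.multitest import multipletests

        for _ in range(30):
            p = rng.uniform(0, 1, rng.integers(3, 20))
            rej_sm, q_sm, _, _ = multipletests(p, 0.05, method="fdr_bh")
            q_bf, rej_bf = brute_force_bh(p)
            np.testing.assert_allclose(q_sm, q_bf, atol=1e-12)
            np.testing.assert_array_equal(rej_sm, rej_bf)
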