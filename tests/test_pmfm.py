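"""Mean-field model: parameterization, dynamics, BOLD, fitting machinery."""

import numpy as np
import pytest
from scipy.optimize import brentq

from eibm import conndyn, pmfm


@pytest.fixture(scope="module")
def substrate():
    from eibm.experiments import make_substrate

    parc, conn, mye, grad = make_substrate(20, seed=3)
    return conn, mye, grad


class TestRegionalParams:
    def test_constant_maps(self, substrate):
        _, mye, grad = substrate
        theta = pmfm.MFMTheta(0, 0, 0.5, 0, 0, 0.3, 0, 0, 0.005, 1.0)
        p = pmfm.regional_params(theta, mye, grad)
        np.testing.assert_allclose(p.w, 0.5)
        np.testing.assert_allclose(p.I, 0.3)

    def test_identity_on_myelin(self, substrate):
        _, mye, grad = substrate
        theta = pmfm.MFMTheta(1, 0, 0, 0, 0, 0.3, 0, 0, 0.005, 1.0)
        with pytest.raises(pmfm.InvalidThetaError):
            # z-scored myelin goes negative, so w < 0 somewhere
            pmfm.regional_params(theta, mye, grad)
        theta = pmfm.MFMTheta(1, 0, 5.0, 0, 0, 0.3, 0, 0, 0.005, 1.0)
        p = pmfm.regional_params(theta, mye, grad)
        np.testing.assert_allclose(p.w, mye + 5.0)

    def test_negative_sigma_rejected(self, substrate):
        _, mye, grad = substrate
        theta = pmfm.MFMTheta(0, 0, 0.5, 0, 0, 0.3, 0, 0, -0.1, 1.0)
        with pytest.raises(pmfm.InvalidThetaError, match="sigma"):
            pmfm.regional_params(theta, mye, grad)


class TestTransferRate:
    def test_removable_singularity(self):
        tc = pmfm.TransferConstants()
        x_star = tc.b / tc.a
        assert pmfm.transfer_rate(x_star) == pytest.approx(1 / tc.d_t, rel=1e-9)
        assert 1 / tc.d_t == pytest.approx(6.4935, abs=1e-3)

    def test_direct_evaluation(self):
        tc = pmfm.TransferConstants()
        x = (tc.b + 10) / tc.a  # a x - b = 10
        expected = 10 / (1 - np.exp(-tc.d_t * 10))
        assert pmfm.transfer_rate(x) == pytest.approx(expected, abs=1e-3)
        assert expected == pytest.approx(12.75, abs=0.03)

    def test_monotone(self):
        xs = np.linspace(-2, 2, 401)
        r = pmfm.transfer_rate(xs)
        assert (np.diff(r) >= -1e-12).all()


class TestSimulate:
    def test_noiseless_fixed_point(self):
        """sigma = 0, G = 0: S converges to the root of the scalar
        self-consistency equation, cross-checked with brentq."""
        tc = pmfm.TransferConstants()
        w, i_ext = 0.5, 0.3
        params = pmfm.CircuitParams(
            w=np.array([w]), I=np.array([i_ext]), sigma=np.array([1e-300])
        )
        s = pmfm.simulate(params, np.zeros((1, 1)), 0.0, duration=60,
                          burn_in=0, seed=0)

        def resid(S):
            x = w * tc.J * S + i_ext
            return float(-S / tc.tau_s + tc.gamma_k * (1 - S) * pmfm.transfer_rate(x))

        root = brentq(resid, 1e-9, 0.2, xtol=1e-12)
        assert s[-1, 0] == pytest.approx(root, abs=1e-6)

    def test_identical_regions_symmetric(self):
        n = 6
        params = pmfm.CircuitParams(
            w=np.full(n, 0.5), I=np.full(n, 0.3), sigma=np.full(n, 1e-300)
        )
        sc = np.ones((n, n)) - np.eye(n)
        s = pmfm.simulate(params, sc, 1.0, duration=30, burn_in=0, seed=1)
        np.testing.assert_allclose(s, s[:, [0]] * np.ones(n), atol=1e-12)

    def test_deterministic_under_seed(self, substrate):
        conn, mye, grad = substrate
        theta = pmfm.MFMTheta(0, 0, 0.9, 0, 0, 0.3, 0, 0, 0.005, 0.3)
        p = pmfm.regional_params(theta, mye, grad)
        a = pmfm.simulate(p, conn.sc, 0.3, duration=20, burn_in=5, seed=7)
        b = pmfm.simulate(p, conn.sc, 0.3, duration=20, burn_in=5, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_bounds_and_clamp_rate(self, substrate):
        conn, mye, grad = substrate
        from eibm.experiments import PREMISE_G, PREMISE_I, PREMISE_SIGMA, PREMISE_W

        n = conn.sc.shape[0]
        params = pmfm.CircuitParams(
            w=np.full(n, PREMISE_W), I=np.full(n, PREMISE_I),
            sigma=np.full(n, PREMISE_SIGMA),
        )
        s, info = pmfm.simulate(params, conn.sc, PREMISE_G, duration=120,
                                burn_in=10, seed=2, return_info=True)
        assert s.min() >= 0 and s.max() <= 1
        assert info["clamp_fraction"] < 0.001

    def test_g_zero_regions_independent(self):
        """Without coupling, long-run BOLD correlations vanish."""
        n = 8
        rng_w = np.random.default_rng(0)
        params = pmfm.CircuitParams(
            w=rng_w.uniform(0.4, 0.9, n), I=np.full(n, 0.3), sigma=np.full(n, 0.005)
        )
        s = pmfm.simulate(params, np.zeros((n, n)), 0.0, duration=1230,
                          burn_in=10, seed=3)
        b = pmfm.bold(s)[50:]
        fc = conndyn.static_fc(b)
        off = fc[np.triu_indices(n, 1)]
        assert abs(off.mean()) < 0.05


class TestBold:
    def test_constant_drive_steady_state(self):
        s = np.full((30_000, 2), 0.1)
        b = pmfm.bold(s)
        late = b[-50:]
        assert late.std(axis=0).max() < 1e-6

    def test_impulse_response_returns_to_baseline(self):
        s = np.zeros((6000, 1))
        s[500:550] = 0.5  # 0.5 s impulse
        b = pmfm.bold(s)  # TR 0.6 -> 60 samples
        peak = np.argmax(b[:, 0])
        assert 8 <= peak <= 30  # peak within ~5-18 s of onset
        assert abs(b[-1, 0]) < 0.05 * b[peak, 0]  # back near baseline by 36 s
        # single-peaked: one sign change in the smoothed derivative
        assert b[peak, 0] > 0

    def test_tr_controls_sampling(self):
        s = np.zeros((12_000, 1))
        b1 = pmfm.bold(s, hc=pmfm.HemodynamicConstants(tr=0.6))
        b2 = pmfm.bold(s, hc=pmfm.HemodynamicConstants(tr=1.2))
        assert len(b1) == 2 * len(b2)

    def test_out_of_range_gating_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            pmfm.bold(np.full((100, 1), 1.5))


class TestFitCost:
    def test_self_comparison_is_zero(self, substrate):
        conn, mye, grad = substrate
        theta = pmfm.MFMTheta(0, 0, 0.9, 0, 0, 0.3, 0, 0, 0.005, 0.3)
        st = pmfm.SimSettings(n_tr=150)
        shell = pmfm.GroupData(conn.sc, mye, grad, None, None)
        b = pmfm.simulate_bold_from_theta(theta, shell, st, seed=9)
        data = pmfm.GroupData(
            conn.sc, mye, grad, conndyn.static_fc(b),
            conndyn.fcd_cdf(conndyn.sliding_window_fcd(b, 100)),
        )
        cost, r, ks = pmfm.fit_cost(theta, data, st, seed=9)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert ks == 0.0
        assert cost == pytest.approx(0.0, abs=1e-12)

    def test_invalid_theta_infinite(self, substrate):
        conn, mye, grad = substrate
        bad = pmfm.MFMTheta(0, 0, 0.9, 0, 0, 0.3, 0, 0, -0.1, 0.3)
        data = pmfm.GroupData(conn.sc, mye, grad, np.eye(20),
                              conndyn.EmpiricalCDF.from_samples(np.array([0.5])))
        cost, r, ks = pmfm.fit_cost(bad, data, pmfm.SimSettings(n_tr=120))
        assert np.isinf(cost)

    def test_cost_range(self, substrate):
        conn, mye, grad = substrate
        theta = pmfm.MFMTheta(0, 0, 0.9, 0, 0, 0.3, 0, 0, 0.005, 0.3)
        st = pmfm.SimSettings(n_tr=150)
        shell = pmfm.GroupData(conn.sc, mye, grad, None, None)
        b = pmfm.simulate_bold_from_theta(theta, shell, st, seed=1)
        data = pmfm.GroupData(
            conn.sc, mye, grad, conndyn.static_fc(b),
            conndyn.fcd_cdf(conndyn.sliding_window_fcd(b, 100)),
        )
        cost, _, _ = pmfm.fit_cost(theta, data, st, seed=2)
        assert 0 <= cost <= 3


class TestCMAES:
    def test_minimizes_shifted_sphere(self):
        target = np.arange(10) / 10.0
        bests = pmfm.cmaes_minimize(
            lambda x: float(np.sum((x - target) ** 2)),
            x0=np.zeros(10), sigma0=0.5, n_iterations=60, popsize=10, seed=0,
        )
        assert bests[-1][1] < 1e-3

    def test_best_so_far_trace_non_increasing(self):
        bests = pmfm.cmaes_minimize(
            lambda x: float(np.sum(x**2)), np.ones(4), 0.3,
            n_iterations=20, popsize=6, seed=1,
        )
        trace = np.minimum.accumulate([b[1] for b in bests])
        assert (np.diff(trace) <= 0).all()

    def test_deterministic(self):
        f = lambda x: float(np.sum(x**2))  # noqa: E731
        a = pmfm.cmaes_minimize(f, np.ones(3), 0.3, 10, 6, seed=5)
        b = pmfm.cmaes_minimize(f, np.ones(3), 0.3, 10, 6, seed=5)
        for (xa, fa), (xb, fb) in zip(a, b):
            np.testing.assert_array_equal(xa, xb)
            assert fa == fb

    def test_infinite_region_handled(self):
        def f(x):
            return np.inf if x[0] < 0 else float(np.sum(x**2))

        bests = pmfm.cmaes_minimize(f, np.full(3, 0.5), 0.3, 30, 8, seed=2)
        assert np.isfinite(bests[-1][1])
        assert bests[-1][1] < 0.1


def test_split_subjects_ratios():
    tr, va, te = pmfm.split_subjects(40, seed=0)
    assert (len(tr), len(va), len(te)) == (15, 15, 10)
    assert len(set(tr) | set(va) | set(te)) == 40
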