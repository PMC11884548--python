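"""Parametric mean-field model (pMFM) of whole-brain dynamics.

Each cortical region is a reduced excitatory population with a single
synaptic gating variable S_i driven by four currents: recurrent input
(strength w_i), long-range input through the structural connectome scaled
by a global coupling G, a constant external input I_i, and Gaussian noise
of amplitude sigma_i. The regional parameters are not free: they are
linear combinations of two cortical annotation maps (a myelin proxy and
the principal FC gradient),

    w_i     = a_w * Mye_i + b_w * Grad_i + c_w
    I_i     = a_I * Mye_i + b_I * Grad_i + c_I
    sigma_i = a_s * Mye_i + b_s * Grad_i + c_s

leaving 10 global unknowns (the nine linear coefficients plus G). Gating
dynamics are integrated with Euler-Maruyama, passed through a
Balloon-Windkessel hemodynamic model to produce BOLD, and the unknowns are
fitted by CMA-ES against empirical static FC (Pearson r of upper
triangles) and FCD (Kolmogorov-Smirnov distance of CDFs) with overall cost
(1 - r) + KS.

The transfer-function and gating constants follow the standard reduced
Wong-Wang lineage; they are configuration, not fitted quantities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from eibm.conndyn import (
    EmpiricalCDF,
    fcd_cdf,
    group_fc,
    group_fcd_cdf,
    ks_distance,
    sliding_window_fcd,
    static_fc,
)

__all__ = [
    "MFMTheta",
    "CircuitParams",
    "TransferConstants",
    "HemodynamicConstants",
    "SimSettings",
    "GroupData",
    "FitBudget",
    "SearchSpace",
    "SplitFit",
    "FitResult",
    "InvalidThetaError",
    "regional_params",
    "transfer_rate",
    "simulate",
    "bold",
    "simulate_bold_from_theta",
    "fit_cost",
    "cmaes_minimize",
    "fit_single_split",
    "cmaes_fit",
    "split_subjects",
]

logger = logging.getLogger(__name__)


class InvalidThetaError(ValueError):
    """Raised when a parameter set induces non-physical regional values."""


@dataclass
class MFMTheta:
    """The 10 global unknowns: linear coefficients for w, I, sigma plus G."""

    a_w: float
    b_w: float
    c_w: float
    a_I: float
    b_I: float
    c_I: float
    a_s: float
    b_s: float
    c_s: float
    G: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.a_w, self.b_w, self.c_w, self.a_I, self.b_I, self.c_I,
             self.a_s, self.b_s, self.c_s, self.G]
        )

    @classmethod
    def from_array(cls, x: np.ndarray) -> "MFMTheta":
        x = np.asarray(x, dtype=float)
        if len(x) != 10 or not np.all(np.isfinite(x)):
            raise ValueError("theta must be 10 finite scalars")
        return cls(*[float(v) for v in x])


@dataclass
class CircuitParams:
    """Induced per-region parameters of the mean-field equations."""

    w: np.ndarray  # recurrent connection strength
    I: np.ndarray  # external input current (nA)
    sigma: np.ndarray  # noise amplitude


@dataclass
class TransferConstants:
    """Population firing-rate transfer and gating constants.

    Standard reduced-model values: gain a (Hz/nA), threshold b (Hz),
    curvature d_t (s), synaptic time constant tau_s (s), rate scaling
    gamma_k, synaptic coupling J (nA).
    """

    a: float = 270.0
    b: float = 108.0
    d_t: float = 0.154
    tau_s: float = 0.1
    gamma_k: float = 0.641
    J: float = 0.2609


@dataclass
class HemodynamicConstants:
    """Balloon-Windkessel forward model constants (Friston lineage).

    kappa: signal decay (1/s); gamma_h: flow autoregulation (1/s);
    tau: transit time (s); alpha: vessel stiffness; E0: resting oxygen
    extraction fraction; V0: resting venous volume fraction; tr: output
    sampling interval (s).
    """

    kappa: float = 0.65
    gamma_h: float = 0.41
    tau: float = 0.98
    alpha: float = 0.32
    E0: float = 0.34
    V0: float = 0.02
    tr: float = 0.6

    @property
    def k1(self) -> float:
        return 7.0 * self.E0

    @property
    def k2(self) -> float:
        return 2.0

    @property
    def k3(self) -> float:
        return 2.0 * self.E0 - 0.2


def regional_params(
    theta: MFMTheta, myelin: np.ndarray, gradient: np.ndarray
) -> CircuitParams:
    """Map the 10 global coefficients to per-region (w, I, sigma).

    Raises :class:`InvalidThetaError` if any induced sigma_i <= 0 or
    w_i < 0; the fitting loop treats that as infinite cost.
    """
    myelin = np.asarray(myelin, dtype=float)
    gradient = np.asarray(gradient, dtype=float)
    if myelin.shape != gradient.shape:
        raise ValueError("annotation maps must have the same length")
    w = theta.a_w * myelin + theta.b_w * gradient + theta.c_w
    i_ext = theta.a_I * myelin + theta.b_I * gradient + theta.c_I
    sigma = theta.a_s * myelin + theta.b_s * gradient + theta.c_s
    if np.any(sigma <= 0):
        raise InvalidThetaError("induced sigma_i <= 0 in some region")
    if np.any(w < 0):
        raise InvalidThetaError("induced w_i < 0 in some region")
    return CircuitParams(w=w, I=i_ext, sigma=sigma)


def transfer_rate(x: np.ndarray, tc: TransferConstants | None = None) -> np.ndarray:
    """Population firing rate r(x) = (a x - b) / (1 - exp(-d (a x - b))).

    Continuous at a x = b with the removable-singularity value 1 / d.
    """
    tc = tc or TransferConstants()
    y = tc.a * np.asarray(x, dtype=float) - tc.b
    dy = tc.d_t * y
    with np.errstate(over="ignore", invalid="ignore"):
        out = np.where(
            np.abs(dy) < 1e-8,
            1.0 / tc.d_t + y / 2.0,
            y / (1.0 - np.exp(-np.clip(dy, -700, 700))),
        )
    return out


@njit(cache=True)
def _integrate_mfm(s0, w, i_ext, sigma, coupling, a, b, d, tau_s, gamma_k, j_c,
                   dt, noise, out):  # pragma: no cover - jitted
    n_steps, n = noise.shape
    s = s0.copy()
    n_clamp = 0
    sqdt = np.sqrt(dt)
    for t in range(n_steps):
        x = j_c * w * s + coupling @ s + i_ext
        for i in range(n):
            y = a * x[i] - b
            dy = d * y
            if abs(dy) < 1e-8:
                r = 1.0 / d + y / 2.0
            elif dy < -50.0:
                r = 0.0
            elif dy > 50.0:
                r = y
            else:
                r = y / (1.0 - np.exp(-dy))
            si = s[i] + (-s[i] / tau_s + gamma_k * (1.0 - s[i]) * r) * dt \
                + sigma[i] * sqdt * noise[t, i]
            if si < 0.0:
                si = 0.0
                n_clamp += 1
            elif si > 1.0:
                si = 1.0
                n_clamp += 1
            s[i] = si
            out[t, i] = si
    return n_clamp


def simulate(
    params: CircuitParams,
    sc: np.ndarray,
    G: float,
    tc: TransferConstants | None = None,
    duration: float = 300.0,
    dt: float = 0.01,
    burn_in: float = 30.0,
    seed: int | None = None,
    s_init: float = 0.2,
    sc_norm: str = "row",
    return_info: bool = False,
):
    """Euler-Maruyama integration of the coupled gating equations.

    dS_i = [-S_i/tau_s + gamma_k (1 - S_i) r(x_i)] dt + sigma_i dW_i with
    x_i = w_i J S_i + G J sum_j SC_ij S_j + I_i. SC is normalized before
    coupling per ``sc_norm``: "row" (each row sums to 1, so every region
    receives unit total long-range input and the bifurcation structure is
    stable across connectome realizations), "max" (divided by the global
    maximum), or "none". S is clamped to [0, 1]; clamping is counted and
    logged. Burn-in is discarded. Times are in seconds.
    """
    tc = tc or TransferConstants()
    if dt > 0.010001:
        raise ValueError("dt must be <= 10 ms for stability")
    sc = np.asarray(sc, dtype=float)
    n = sc.shape[0]
    if sc_norm == "row":
        rows = sc.sum(axis=1, keepdims=True)
        rows[rows == 0] = 1.0
        sc_scaled = sc / rows
    elif sc_norm == "max":
        sc_scaled = sc / sc.max() if sc.max() > 0 else sc
    elif sc_norm == "none":
        sc_scaled = sc
    else:
        raise ValueError(f"unknown sc_norm {sc_norm!r}")
    coupling = G * tc.J * sc_scaled
    n_burn = int(round(burn_in / dt))
    n_keep = int(round(duration / dt))
    n_steps = n_burn + n_keep
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_steps, n))
    out = np.empty((n_steps, n))
    s0 = np.full(n, float(s_init))
    n_clamp = _integrate_mfm(
        s0, params.w.astype(float), params.I.astype(float),
        params.sigma.astype(float), coupling, tc.a, tc.b, tc.d_t,
        tc.tau_s, tc.gamma_k, tc.J, dt, noise, out,
    )
    s_series = out[n_burn:]
    if not np.all(np.isfinite(s_series)):
        bad = int(np.argwhere(~np.isfinite(out))[0, 0])
        raise FloatingPointError(f"non-finite gating state at step {bad}")
    clamp_frac = n_clamp / (n_steps * n)
    if clamp_frac > 0:
        logger.debug("clamped %.4f%% of integration steps", 100 * clamp_frac)
    if return_info:
        return s_series, {"clamp_fraction": clamp_frac}
    return s_series


@njit(cache=True)
def _integrate_bw(s_series, dt, kappa, gamma_h, tau, alpha, e0, v0,
                  k1, k2, k3, stride, out):  # pragma: no cover - jitted
    n_steps, n = s_series.shape
    z = np.zeros(n)
    f = np.ones(n)
    v = np.ones(n)
    q = np.ones(n)
    ia = 1.0 / alpha
    m = 0
    for t in range(n_steps):
        for i in range(n):
            fi = f[i] if f[i] > 1e-6 else 1e-6
            vi = v[i] if v[i] > 1e-6 else 1e-6
            via = vi**ia
            dz = s_series[t, i] - kappa * z[i] - gamma_h * (fi - 1.0)
            dv = (fi - via) / tau
            e_f = 1.0 - (1.0 - e0) ** (1.0 / fi)
            dq = (fi * e_f / e0 - via * q[i] / vi) / tau
            z[i] += dz * dt
            f[i] += z[i] * dt
            v[i] += dv * dt
            q[i] += dq * dt
        if (t + 1) % stride == 0 and m < out.shape[0]:
            for i in range(n):
                vi = v[i] if v[i] > 1e-6 else 1e-6
                out[m, i] = v0 * (k1 * (1.0 - q[i]) + k2 * (1.0 - q[i] / vi)
                                  + k3 * (1.0 - vi))
            m += 1
    return m


def bold(
    s_series: np.ndarray, dt: float = 0.01, hc: HemodynamicConstants | None = None
) -> np.ndarray:
    """Balloon-Windkessel BOLD from a gating series, downsampled to TR.

    Integrates the four hemodynamic states (vasodilatory signal, inflow,
    venous volume, deoxyhemoglobin) per region at the integration dt,
    driven by S, and samples the nonlinear BOLD readout every TR.
    """
    hc = hc or HemodynamicConstants()
    s_series = np.asarray(s_series, dtype=float)
    if s_series.min() < 0 or s_series.max() > 1:
        raise ValueError("gating input must lie in [0, 1]")
    stride = int(round(hc.tr / dt))
    n_out = s_series.shape[0] // stride
    out = np.empty((n_out, s_series.shape[1]))
    m = _integrate_bw(
        s_series, dt, hc.kappa, hc.gamma_h, hc.tau, hc.alpha, hc.E0, hc.V0,
        hc.k1, hc.k2, hc.k3, stride, out,
    )
    out = out[:m]
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite hemodynamic state")
    return out


@dataclass
class SimSettings:
    """Length/resolution of each candidate-evaluation simulation."""

    n_tr: int = 400  # simulated BOLD samples per evaluation
    tr: float = 0.6  # s
    dt: float = 0.01  # s
    burn_in: float = 30.0  # neural burn-in discarded before BOLD (s)
    hemo_settle: float = 30.0  # hemodynamic transient discarded from BOLD (s)
    window_length: int = 100  # FCD window, in TR samples
    s_init: float = 0.1  # initial gating (low-activity basin)
    sc_norm: str = "row"  # SC normalization before coupling
    n_avg: int = 1  # noise paths averaged per cost evaluation

    @property
    def duration(self) -> float:
        return self.n_tr * self.tr + self.hemo_settle


@dataclass
class GroupData:
    """Empirical targets and substrate for one fit: SC, maps, FC, FCD CDF."""

    sc: np.ndarray
    myelin: np.ndarray
    gradient: np.ndarray
    fc_emp: np.ndarray
    fcd_cdf_emp: EmpiricalCDF


def simulate_bold_from_theta(
    theta: MFMTheta,
    data: GroupData,
    settings: SimSettings,
    seed: int | None = None,
    tc: TransferConstants | None = None,
) -> np.ndarray:
    """Convenience path theta -> regional params -> gating -> BOLD."""
    params = regional_params(theta, data.myelin, data.gradient)
    hc = HemodynamicConstants(tr=settings.tr)
    s = simulate(
        params, data.sc, theta.G,
        tc=tc, duration=settings.duration, dt=settings.dt,
        burn_in=settings.burn_in, seed=seed, s_init=settings.s_init,
        sc_norm=settings.sc_norm,
    )
    b = bold(s, dt=settings.dt, hc=hc)
    # drop the hemodynamic settling transient, keep n_tr samples
    n_settle = int(round(settings.hemo_settle / settings.tr))
    return b[n_settle : n_settle + settings.n_tr]


# box on induced regional values used during fitting
W_MAX = 1.5
SIGMA_MAX = 0.02


def fit_cost(
    theta: MFMTheta,
    data: GroupData,
    settings: SimSettings | None = None,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Overall model-fit cost (1 - r) + KS for one parameter set.

    r is the Pearson correlation between the upper triangles of simulated
    and empirical static FC; KS is the Kolmogorov-Smirnov distance between
    simulated and empirical FCD CDFs. With ``settings.n_avg`` > 1 the
    simulated FC (Fisher-z) and FCD CDF are averaged over that many noise
    paths before comparison, reducing evaluation noise. Invalid parameter
    sets (non-physical induced regional values, numerical blow-up,
    degenerate output) return infinite cost instead of raising.
    """
    settings = settings or SimSettings()
    try:
        params = regional_params(theta, data.myelin, data.gradient)
    except InvalidThetaError:
        return np.inf, np.nan, np.nan
    if np.any(params.w > W_MAX) or np.any(params.sigma > SIGMA_MAX):
        return np.inf, np.nan, np.nan
    base_seed = 0 if seed is None else int(seed)
    fcs, cdfs = [], []
    try:
        for k in range(settings.n_avg):
            sim = simulate_bold_from_theta(theta, data, settings, seed=base_seed + k)
            if np.any(sim.std(axis=0) == 0):
                return np.inf, np.nan, np.nan
            fcs.append(static_fc(sim))
            cdfs.append(fcd_cdf(sliding_window_fcd(sim, settings.window_length)))
    except FloatingPointError as exc:
        logger.info("simulation failed for theta (%s); infinite cost", exc)
        return np.inf, np.nan, np.nan
    fc_sim = fcs[0] if len(fcs) == 1 else group_fc(fcs)
    cdf_sim = cdfs[0] if len(cdfs) == 1 else group_fcd_cdf(cdfs)
    iu = np.triu_indices(fc_sim.shape[0], 1)
    r = float(np.corrcoef(fc_sim[iu], data.fc_emp[iu])[0, 1])
    ks = ks_distance(cdf_sim, data.fcd_cdf_emp)
    if not np.isfinite(r):
        return np.inf, np.nan, np.nan
    return (1.0 - r) + ks, r, ks


def cmaes_minimize(
    f,
    x0: np.ndarray,
    sigma0: float,
    n_iterations: int,
    popsize: int,
    seed: int | None = None,
) -> list[tuple[np.ndarray, float]]:
    """Minimal (mu/mu_w, lambda)-CMA-ES; returns per-generation bests.

    Standard Hansen formulation with rank-one and rank-mu covariance
    updates and cumulative step-size adaptation. Infinite objective values
    are ranked last.
    """
    rng = np.random.default_rng(seed)
    n = len(x0)
    mu = popsize // 2
    wts = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    wts /= wts.sum()
    mueff = 1.0 / np.sum(wts**2)
    cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
    cs = (mueff + 2) / (n + mueff + 5)
    c1 = 2 / ((n + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
    damps = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (n + 1)) - 1) + cs
    chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))

    mean = np.asarray(x0, dtype=float).copy()
    sigma = float(sigma0)
    cov = np.eye(n)
    pc = np.zeros(n)
    ps = np.zeros(n)
    bests: list[tuple[np.ndarray, float]] = []

    for gen in range(n_iterations):
        evals, vecs = np.linalg.eigh(cov)
        evals = np.clip(evals, 1e-14, None)
        sqrt_c = vecs @ np.diag(np.sqrt(evals)) @ vecs.T
        invsqrt_c = vecs @ np.diag(1.0 / np.sqrt(evals)) @ vecs.T
        zs = rng.standard_normal((popsize, n))
        ys = zs @ sqrt_c.T
        xs = mean + sigma * ys
        fs = np.array([f(x) for x in xs])
        order = np.argsort(fs)
        bests.append((xs[order[0]].copy(), float(fs[order[0]])))

        sel = xs[order[:mu]]
        mean_new = wts @ sel
        step = (mean_new - mean) / sigma
        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mueff) * (invsqrt_c @ step)
        hsig = (
            np.linalg.norm(ps) / np.sqrt(1 - (1 - cs) ** (2 * (gen + 1))) / chi_n
            < 1.4 + 2 / (n + 1)
        )
        pc = (1 - cc) * pc + hsig * np.sqrt(cc * (2 - cc) * mueff) * step
        artmp = (sel - mean) / sigma
        cov = (
            (1 - c1 - cmu) * cov
            + c1 * (np.outer(pc, pc) + (1 - hsig) * cc * (2 - cc) * cov)
            + cmu * artmp.T @ np.diag(wts) @ artmp
        )
        sigma *= np.exp((cs / damps) * (np.linalg.norm(ps) / chi_n - 1))
        sigma = min(sigma, 1e3)
        mean = mean_new
    return bests


@dataclass
class SearchSpace:
    """Affine reparameterization theta = base + scales * z for the search.

    Chosen so z ~ N(0, I) induces mid-range regional maps: the constant
    terms give w ~ 0.5, I ~ 0.3 nA, sigma ~ 5e-3, G ~ 1 at z = 0.
    """

    base: np.ndarray = field(
        default_factory=lambda: np.array(
            [0.0, 0.0, 0.5, 0.0, 0.0, 0.3, 0.0, 0.0, 0.005, 1.0]
        )
    )
    scales: np.ndarray = field(
        default_factory=lambda: np.array(
            [0.2, 0.2, 0.3, 0.1, 0.1, 0.15, 0.002, 0.002, 0.003, 0.5]
        )
    )

    def theta(self, z: np.ndarray) -> MFMTheta:
        return MFMTheta.from_array(self.base + self.scales * np.asarray(z))


@dataclass
class FitBudget:
    n_iterations: int = 50
    n_restarts: int = 5
    popsize: int = 8
    top_k: int = 10


@dataclass
class SplitFit:
    """Outcome of the train/validate/test protocol on one subject split."""

    theta: MFMTheta
    train_cost: float
    val_cost: float
    test_cost: float
    test_r: float
    test_ks: float
    traces: list[np.ndarray]  # per-restart best-so-far training cost


@dataclass
class FitResult:
    splits: list[SplitFit]
    theta_mean: MFMTheta


def fit_single_split(
    train: GroupData,
    val: GroupData,
    test: GroupData,
    budget: FitBudget | None = None,
    settings: SimSettings | None = None,
    space: SearchSpace | None = None,
    seed: int | None = None,
) -> SplitFit:
    """CMA-ES on the training cost; candidates re-scored on validation,
    the top-k re-scored on test; the best test-cost theta wins.

    One candidate (the generation best) is kept per CMA-ES iteration, so
    n_iterations x n_restarts candidates enter validation scoring. The
    simulation noise path is fixed per split (common random numbers) so
    the search surface is deterministic.
    """
    budget = budget or FitBudget()
    settings = settings or SimSettings()
    space = space or SearchSpace()
    ss = np.random.SeedSequence(seed)
    sim_seed, val_seed, test_seed, *restart_seeds = [
        int(s.generate_state(1)[0] % 2**31)
        for s in ss.spawn(3 + budget.n_restarts)
    ]

    def train_cost_of(z: np.ndarray) -> float:
        try:
            theta = space.theta(z)
        except ValueError:
            return np.inf
        return fit_cost(theta, train, settings, seed=sim_seed)[0]

    # multistart design: restarts begin in different sign quadrants of the
    # map coefficients (a_w, b_w), since the cost surface can hold separate
    # basins for a regional pattern and its spatial inversion
    offsets = [
        np.zeros(10),
        np.array([1.5, -0.5, 0, 0, 0, 0, 0, 0, 0, 0]),
        np.array([-1.5, 0.5, 0, 0, 0, 0, 0, 0, 0, 0]),
        np.array([0.5, 1.5, 0, 0, 0, 0, 0, 0, 0, 0]),
        np.array([-0.5, -1.5, 0, 0, 0, 0, 0, 0, 0, 0]),
    ]
    candidates: list[tuple[np.ndarray, float]] = []
    traces: list[np.ndarray] = []
    for r in range(budget.n_restarts):
        rng_r = np.random.default_rng(restart_seeds[r])
        z0 = offsets[r % len(offsets)] + rng_r.standard_normal(10) * 0.25
        bests = cmaes_minimize(
            train_cost_of, z0, sigma0=0.5,
            n_iterations=budget.n_iterations, popsize=budget.popsize,
            seed=restart_seeds[r],
        )
        candidates.extend(bests)
        traces.append(np.minimum.accumulate([b[1] for b in bests]))

    finite = [c for c in candidates if np.isfinite(c[1])]
    if not finite:
        raise RuntimeError(
            "all CMA-ES candidates had infinite cost; review search-space "
            "base/scales and induced-parameter bounds"
        )
    val_scored = []
    for z, _ in finite:
        theta = space.theta(z)
        val_scored.append((fit_cost(theta, val, settings, seed=val_seed)[0], z))
    val_scored.sort(key=lambda t: t[0])
    top = val_scored[: budget.top_k]

    best = None
    for vcost, z in top:
        theta = space.theta(z)
        tcost, tr_, tks = fit_cost(theta, test, settings, seed=test_seed)
        if best is None or tcost < best[0]:
            best = (tcost, tr_, tks, vcost, z)
    tcost, tr_, tks, vcost, z = best
    return SplitFit(
        theta=space.theta(z),
        train_cost=float(train_cost_of(z)),
        val_cost=float(vcost),
        test_cost=float(tcost),
        test_r=float(tr_),
        test_ks=float(tks),
        traces=traces,
    )


def cmaes_fit(
    splits: list[tuple[GroupData, GroupData, GroupData]],
    budget: FitBudget | None = None,
    settings: SimSettings | None = None,
    space: SearchSpace | None = None,
    seed: int | None = None,
) -> FitResult:
    """Run the split protocol over every (train, val, test) triple and
    average the winning parameter sets into the group-representative theta.
    """
    if not splits:
        raise ValueError("need at least one (train, val, test) split")
    ss = np.random.SeedSequence(seed)
    split_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(len(splits))]
    results = [
        fit_single_split(tr, va, te, budget, settings, space, seed=sd)
        for (tr, va, te), sd in zip(splits, split_seeds)
    ]
    theta_mean = MFMTheta.from_array(
        np.mean([r.theta.as_array() for r in results], axis=0)
    )
    return FitResult(splits=results, theta_mean=theta_mean)


def split_subjects(
    n_subjects: int,
    fractions: tuple[float, float, float] = (15 / 40, 15 / 40, 10 / 40),
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random train/validation/test index split (15:15:10 ratios)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_subjects)
    n_tr = int(round(fractions[0] * n_subjects))
    n_va = int(round(fractions[1] * n_subjects))
    return perm[:n_tr], perm[n_tr : n_tr + n_va], perm[n_tr + n_va :]
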