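"""Canned simulation experiments that probe the package's core claims.

Two desk-scale studies, used by the test suite and the reproduction
script:

* the excitation/inhibition premise — scaling up recurrent connection
  strength w in a subset of regions lowers the estimated Hurst exponent
  of their simulated BOLD relative to unperturbed regions;
* parameter recovery — the CMA-ES fitting protocol run against
  model-generated group data recovers the spatial pattern of the true
  recurrent-strength map.

The operating points are fixed study conditions: a mixed-excitability
regime (regional w heterogeneous around the bistable threshold) for
recovery, and a saturated hyperexcitable regime with scanner-level
measurement noise for the Hurst premise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from eibm import clf, conndyn, gstats, netmap, pmfm, synthcohort
from eibm.fractal import hurst_map

__all__ = [
    "make_substrate",
    "make_group_data",
    "ei_premise_experiment",
    "recovery_experiment",
    "spin_type1_error",
    "rewired_type1_error",
    "group_term_type1_error",
    "classifier_permutation_type1_error",
    "power_experiment",
    "epicenter_experiment",
    "RECOVERY_THETA",
    "RECOVERY_SPACE",
]


def _spawn_ints(seed, n):
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def make_substrate(
    n_regions: int = 40,
    density: float = 0.3,
    seed: int | None = None,
) -> tuple[synthcohort.Parcellation, synthcohort.Connectome, np.ndarray, np.ndarray]:
    """Parcellation, connectome, and annotation maps for simulation studies."""
    ss = np.random.SeedSequence(seed)
    s1, s2, s3 = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3)]
    parc = synthcohort.make_geometry(n_regions, seed=s1)
    conn = synthcohort.make_connectome(parc, density=density, seed=s2)
    myelin, gradient = synthcohort.make_annotation_maps(parc, seed=s3)
    return parc, conn, myelin, gradient


def make_group_data(
    theta: pmfm.MFMTheta,
    sc: np.ndarray,
    myelin: np.ndarray,
    gradient: np.ndarray,
    settings: pmfm.SimSettings,
    n_subjects: int = 10,
    seed: int | None = None,
) -> pmfm.GroupData:
    """Group-level fit targets from model-generated pseudo-subjects.

    Simulates ``n_subjects`` independent noise paths at ``theta``,
    averages their static FC (Fisher-z) and FCD CDFs, mirroring how
    empirical group targets are built from real participants.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_subjects)]
    shell = pmfm.GroupData(sc=sc, myelin=myelin, gradient=gradient,
                           fc_emp=None, fcd_cdf_emp=None)
    fcs, cdfs = [], []
    for sd in seeds:
        b = pmfm.simulate_bold_from_theta(theta, shell, settings, seed=sd)
        fcs.append(conndyn.static_fc(b))
        cdfs.append(conndyn.fcd_cdf(
            conndyn.sliding_window_fcd(b, settings.window_length)))
    return pmfm.GroupData(
        sc=sc, myelin=myelin, gradient=gradient,
        fc_emp=conndyn.group_fc(fcs),
        fcd_cdf_emp=conndyn.group_fcd_cdf(cdfs),
    )


# --- E/I premise -----------------------------------------------------------

#: Operating point for the premise experiment: all regions share a
#: hyperexcitable saturated state; scaling w deepens saturation, which
#: shrinks and speeds BOLD fluctuations relative to measurement noise.
PREMISE_W = 0.9
PREMISE_I = 0.325
PREMISE_G = 0.3
PREMISE_SIGMA = 0.005
PREMISE_MEASUREMENT_NOISE = 5e-6


def ei_premise_experiment(
    n_seeds: int = 10,
    n_regions: int = 40,
    w_scale: float = 1.3,
    duration: float = 430.0,
    seed: int | None = None,
) -> dict:
    """Does raising recurrent strength w lower the estimated Hurst exponent?

    Runs paired simulations in which half the regions have w scaled by
    ``w_scale``; per seed, compares the mean estimated H of perturbed vs
    unperturbed regions, and reports a one-sided paired t-test for
    H_perturbed < H_unperturbed. Measurement noise at a fixed scanner
    level is added to the BOLD readout before estimation.
    """
    ss = np.random.SeedSequence(seed)
    sub_seed = int(ss.generate_state(1)[0] % 2**31)
    parc, conn, _, _ = make_substrate(n_regions, seed=sub_seed)
    half = n_regions // 2
    w = np.full(n_regions, PREMISE_W)
    perturbed = np.arange(half)
    w[perturbed] *= w_scale
    params = pmfm.CircuitParams(
        w=w, I=np.full(n_regions, PREMISE_I), sigma=np.full(n_regions, PREMISE_SIGMA)
    )
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_seeds)]
    h_pert, h_unpert = [], []
    for sd in seeds:
        s = pmfm.simulate(params, conn.sc, PREMISE_G, duration=duration,
                          burn_in=0, seed=sd, s_init=0.1)
        b = pmfm.bold(s)[50:]  # drop hemodynamic settling (30 s at TR 0.6)
        rng = np.random.default_rng(sd + 1)
        b = b + PREMISE_MEASUREMENT_NOISE * rng.standard_normal(b.shape)
        h = hurst_map(b)
        h_pert.append(np.nanmean(h[perturbed]))
        h_unpert.append(np.nanmean(h[half:]))
    h_pert = np.array(h_pert)
    h_unpert = np.array(h_unpert)
    t, p_two = stats.ttest_rel(h_pert, h_unpert)
    p_one = p_two / 2 if t < 0 else 1 - p_two / 2
    return {
        "h_perturbed": h_pert,
        "h_unperturbed": h_unpert,
        "mean_difference": float(np.mean(h_pert - h_unpert)),
        "t": float(t),
        "p_one_sided": float(p_one),
    }


# --- parameter recovery ----------------------------------------------------

#: Ground-truth parameter set for the recovery study: heterogeneous w
#: spanning the bistable threshold so the region-state partition (and
#: hence FC) is shaped by the w-map.
RECOVERY_THETA = pmfm.MFMTheta(
    a_w=0.25, b_w=-0.1, c_w=0.95,
    a_I=0.0, b_I=0.0, c_I=0.31,
    a_s=0.0, b_s=0.0, c_s=0.01,
    G=0.3,
)

#: Search reparameterization centered on the mixed-excitability regime.
RECOVERY_SPACE = pmfm.SearchSpace(
    base=np.array([0.0, 0.0, 0.9, 0.0, 0.0, 0.31, 0.0, 0.0, 0.008, 0.4]),
    scales=np.array([0.15, 0.15, 0.2, 0.01, 0.01, 0.02, 0.003, 0.003, 0.004, 0.2]),
)


#: Fixed substrate for the recovery study. Like an atlas, the geometry,
#: connectome and annotation maps are reference objects, not samples: the
#: maps must spread w across the bistable threshold such that the
#: region-state partition is identical across noise paths (verified in the
#: test suite), otherwise group-averaged targets are not identifiable.
RECOVERY_SUBSTRATE_SEED = 42


def recovery_experiment(
    n_regions: int = 40,
    n_tr: int = 400,
    budget: pmfm.FitBudget | None = None,
    n_splits: int = 2,
    n_group_subjects: int = 10,
    n_avg: int = 3,
    seed: int | None = None,
) -> dict:
    """Fit the model to data generated by a known theta and score recovery.

    For each split, independent train/validation/test group targets are
    generated from :data:`RECOVERY_THETA` on the fixed reference
    substrate; the CMA-ES protocol is run and the winning parameter sets
    averaged. ``seed`` drives subject noise, splits and the optimizer.
    Recovery is summarized as the Spearman correlation between the true
    and recovered regional recurrent-strength maps.
    """
    budget = budget or pmfm.FitBudget(n_iterations=20, n_restarts=3)
    ss = np.random.SeedSequence(seed)
    parc, conn, myelin, gradient = make_substrate(
        n_regions, seed=RECOVERY_SUBSTRATE_SEED
    )
    settings = pmfm.SimSettings(n_tr=n_tr, n_avg=n_avg)

    splits = []
    for sp in ss.spawn(n_splits):
        tr_s, va_s, te_s = [int(s.generate_state(1)[0] % 2**31) for s in sp.spawn(3)]
        splits.append(tuple(
            make_group_data(RECOVERY_THETA, conn.sc, myelin, gradient,
                            settings, n_group_subjects, seed=s)
            for s in (tr_s, va_s, te_s)
        ))
    fit_seed = int(ss.generate_state(2)[1] % 2**31)
    result = pmfm.cmaes_fit(splits, budget, settings, RECOVERY_SPACE, seed=fit_seed)

    w_true = pmfm.regional_params(RECOVERY_THETA, myelin, gradient).w
    w_hat = pmfm.regional_params(result.theta_mean, myelin, gradient).w
    rho = float(stats.spearmanr(w_true, w_hat).statistic)
    return {
        "spearman_w": rho,
        "theta_true": RECOVERY_THETA,
        "theta_recovered": result.theta_mean,
        "fit_result": result,
        "w_true": w_true,
        "w_recovered": w_hat,
    }


# --- null calibrations -----------------------------------------------------


def spin_type1_error(
    n_replicates: int = 200,
    n_regions: int = 68,
    n_rotations: int = 500,
    alpha: float = 0.05,
    seed: int | None = None,
) -> float:
    """Empirical type-I rate of the spin test on independent smooth maps."""
    seeds = _spawn_ints(seed, n_replicates + 1)
    parc = synthcohort.make_geometry(n_regions, seed=seeds[-1])
    pearson = lambda a, b: float(np.corrcoef(a, b)[0, 1])  # noqa: E731
    hits = 0
    for k in range(n_replicates):
        rng = np.random.default_rng(seeds[k])
        m1, _ = synthcohort.make_annotation_maps(parc, seed=int(rng.integers(2**31)))
        m2, _ = synthcohort.make_annotation_maps(parc, seed=int(rng.integers(2**31)))
        res = netmap.spin_pvalue(pearson, m1, m2, parc, n=n_rotations,
                                 seed=int(rng.integers(2**31)))
        hits += res.p_value <= alpha
    return hits / n_replicates


def rewired_type1_error(
    n_replicates: int = 100,
    n_null: int = 99,
    alpha: float = 0.05,
    seed: int | None = None,
) -> float:
    """Empirical type-I rate of the rewired-null test on random maps."""
    seeds = _spawn_ints(seed, n_replicates + 1)
    parc = synthcohort.make_geometry(68, seed=seeds[-1])
    conn = synthcohort.make_connectome(parc, density=0.3, seed=seeds[-1])
    hits = 0
    for k in range(n_replicates):
        rng = np.random.default_rng(seeds[k])
        d = rng.standard_normal(68)
        res = netmap.rewired_pvalue(
            netmap.node_neighbor_coupling, d, conn.sc, conn.dist,
            n_null=n_null, seed=int(rng.integers(2**31)),
        )
        hits += res.p_value <= alpha
    return hits / n_replicates


def group_term_type1_error(
    n_replicates: int = 50,
    alpha: float = 0.05,
    seed: int | None = None,
) -> float:
    """Region-wise false-positive rate of the group term on null cohorts.

    Full path: fGn cohorts with delta-H = 0, per-subject Hurst estimation,
    normalization, ipsi-sorting, covariate-adjusted comparison.
    """
    spec = synthcohort.CohortSpec(
        n_controls=16, n_patients=16, n_regions=16, n_timepoints=512,
        affected_regions=(0, 1, 2), delta_h=0.0,
    )
    hits = total = 0
    for sd in _spawn_ints(seed, n_replicates):
        cohort = synthcohort.make_cohort(spec, seed=sd)
        ctrl, pt, age, sex = [], [], [], []
        for s in cohort.subjects:
            h = gstats.flip_to_ipsi(hurst_map(s.ts), s.focus_side, cohort.parcellation)
            (ctrl if s.group == "control" else pt).append(h)
            age.append(s.age)
            sex.append(s.sex)
        pt_z, ctrl_z = gstats.zscore_to_controls(np.array(pt), np.array(ctrl))
        comp = gstats.compare_regions(ctrl_z, pt_z, np.array(age), np.array(sex))
        hits += (comp.p < alpha).sum()
        total += spec.n_regions
    return hits / total


def classifier_permutation_type1_error(
    n_replicates: int = 50,
    n_perm: int = 99,
    alpha: float = 0.05,
    seed: int | None = None,
) -> float:
    """Type-I rate of the classifier permutation test on label-free maps.

    The observed run uses the same CV iteration count as each permutation
    so observed and permuted metrics are exchangeable under the null.
    """
    cfg = clf.ClassifierConfig(k_percent=30, n_folds=4, n_iterations=2)
    hits = 0
    for sd in _spawn_ints(seed, n_replicates):
        rng = np.random.default_rng(sd)
        maps = 0.7 + 0.05 * rng.standard_normal((32, 20))
        labels = np.repeat([0, 1], 16)
        res = clf.permutation_significance(
            maps, labels, cfg, n_perm=n_perm, n_perm_iterations=2,
            seed=int(rng.integers(2**31)),
        )
        hits += res["p_accuracy"] <= alpha
    return hits / n_replicates


# --- positive controls -----------------------------------------------------


def power_experiment(
    n_seeds: int = 10,
    delta_h: float = 0.15,
    n_affected: int = 20,
    n_regions: int = 68,
    n_timepoints: int = 1024,
    seed: int | None = None,
) -> dict:
    """Sensitivity and false-discovery proportion on an effect cohort.

    Patients carry a Hurst decrease of ``delta_h`` in ``n_affected``
    ipsilateral regions; the full estimation-normalization-comparison
    path is run and the q < 0.05 discoveries scored against truth.
    """
    affected = tuple(range(n_affected))
    spec = synthcohort.CohortSpec(
        n_controls=40, n_patients=40, n_regions=n_regions,
        n_timepoints=n_timepoints, affected_regions=affected, delta_h=delta_h,
    )
    n_hit = n_sig = n_false = 0
    for sd in _spawn_ints(seed, n_seeds):
        cohort = synthcohort.make_cohort(spec, seed=sd)
        ctrl, pt, age, sex = [], [], [], []
        for s in cohort.subjects:
            h = gstats.flip_to_ipsi(hurst_map(s.ts), s.focus_side, cohort.parcellation)
            (ctrl if s.group == "control" else pt).append(h)
            age.append(s.age)
            sex.append(s.sex)
        pt_z, ctrl_z = gstats.zscore_to_controls(np.array(pt), np.array(ctrl))
        comp = gstats.compare_regions(ctrl_z, pt_z, np.array(age), np.array(sex))
        sig = np.flatnonzero(comp.significant)
        n_sig += len(sig)
        n_hit += np.isin(sig, affected).sum()
        n_false += (~np.isin(sig, affected)).sum()
    sensitivity = n_hit / (n_seeds * n_affected)
    fdp = n_false / n_sig if n_sig else 0.0
    return {"sensitivity": sensitivity, "fdp": fdp, "n_significant": n_sig}


def epicenter_experiment(
    n_seeds: int = 10,
    n_regions: int = 68,
    n_timepoints: int = 512,
    top_fraction: float = 0.10,
    seed: int | None = None,
) -> dict:
    """Does epicenter mapping localize an SC-neighborhood-seeded effect?

    Per seed, the affected-region set is one seed region plus its
    strongest structural neighbors; success = the seed region or one of
    its graph neighbors ranks in the top 10% of epicenter likelihoods.
    """
    hits = 0
    for sd in _spawn_ints(seed, n_seeds):
        rng = np.random.default_rng(sd)
        parc = synthcohort.make_geometry(n_regions, seed=int(rng.integers(2**31)))
        conn = synthcohort.make_connectome(parc, density=0.3,
                                           seed=int(rng.integers(2**31)))
        half = n_regions // 2
        epicenter = int(rng.integers(half))  # left-hemisphere seed region
        neighbors = np.argsort(-conn.sc[epicenter])[:6]
        affected = tuple({epicenter, *neighbors.tolist()})
        spec = synthcohort.CohortSpec(
            n_controls=20, n_patients=20, n_regions=n_regions,
            n_timepoints=n_timepoints, affected_regions=affected,
            delta_h=0.2, focus_side="L",
        )
        cohort = synthcohort.make_cohort(spec, seed=int(rng.integers(2**31)))
        # patients vs controls on the affected substrate
        ctrl, pt, age, sex = [], [], [], []
        for s in cohort.subjects:
            h = hurst_map(s.ts)
            (ctrl if s.group == "control" else pt).append(h)
            age.append(s.age)
            sex.append(s.sex)
        pt_z, ctrl_z = gstats.zscore_to_controls(np.array(pt), np.array(ctrl))
        comp = gstats.compare_regions(ctrl_z, pt_z, np.array(age), np.array(sex))
        # patients are *lower* in affected regions (d < 0); rank on the
        # alteration magnitude so epicenters get positive likelihood
        res = netmap.epicenter_likelihood(-comp.cohens_d, conn.sc)
        top_k = max(1, int(np.ceil(top_fraction * n_regions)))
        top = np.flatnonzero(res["rank"] <= top_k)
        candidates = {epicenter, *np.flatnonzero(conn.sc[epicenter] > 0).tolist()}
        hits += bool(candidates & set(top.tolist()))
    return {"hit_rate": hits / n_seeds}
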