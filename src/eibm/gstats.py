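"""Region-wise group statistics and clinical associations.

Patient maps are first z-normalized to the control distribution and
hemisphere-sorted so region indices mean ipsilateral/contralateral to the
seizure focus. Group differences are then assessed per region with a
linear model controlling age and sex, summarized as Cohen's d (negative =
lower in patients) with Benjamini-Hochberg FDR across regions. Additional
utilities cover the summary-statistic tests used for demographic tables,
covariate-adjusted partial correlations for cognition, per-network
summaries, and first-principal-component composite scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from eibm.synthcohort import Parcellation

__all__ = [
    "GroupComparison",
    "zscore_to_controls",
    "flip_to_ipsi",
    "compare_regions",
    "summary_ttest",
    "chisq_2x2",
    "partial_corr",
    "network_means",
    "pc1_scores",
]


@dataclass
class GroupComparison:
    """Per-region group contrast with FDR control."""

    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    cohens_d: np.ndarray
    significant: np.ndarray  # boolean mask at q < alpha
    alpha: float
    covariates: tuple[str, ...]


def zscore_to_controls(
    patient_maps: np.ndarray, control_maps: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize every subject's map to the control mean/SD per region.

    Returns (patient_z, control_z). Controls are transformed by their own
    statistics, so their per-region mean is 0 and SD is 1 by construction.
    """
    control_maps = np.atleast_2d(np.asarray(control_maps, dtype=float))
    patient_maps = np.atleast_2d(np.asarray(patient_maps, dtype=float))
    if control_maps.shape[0] < 3:
        raise ValueError("need at least 3 controls for normalization")
    if control_maps.shape[1] != patient_maps.shape[1]:
        raise ValueError("region dimensions differ between groups")
    mu = control_maps.mean(axis=0)
    sd = control_maps.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if len(bad):
        raise ValueError(f"zero control SD in region(s) {bad.tolist()}")
    return (patient_maps - mu) / sd, (control_maps - mu) / sd


def flip_to_ipsi(map_values: np.ndarray, focus_side: str, parc: Parcellation) -> np.ndarray:
    """Reorder hemispheres so indices read (ipsilateral, contralateral).

    Left-focus subjects and controls pass through unchanged; right-focus
    subjects have each region swapped with its homotopic pair. Applying
    the transform twice is the identity.
    """
    map_values = np.asarray(map_values, dtype=float)
    n = parc.n_regions
    if len(map_values) != n:
        raise ValueError("map length does not match parcellation")
    if n % 2 != 0:
        raise ValueError("parcellation lacks complete homotopic pairing")
    if focus_side in ("L", "none"):
        return map_values.copy()
    if focus_side != "R":
        raise ValueError(f"unknown focus side {focus_side!r}")
    half = n // 2
    out = np.empty_like(map_values)
    out[:half] = map_values[half:]
    out[half:] = map_values[:half]
    return out


def _bh(p: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    rej, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, rej


def compare_regions(
    control_maps: np.ndarray,
    patient_maps: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    alpha: float = 0.05,
) -> GroupComparison:
    """Region-wise linear model value ~ group + age + sex, with BH-FDR.

    ``age``/``sex`` are stacked control-then-patient. The group term is
    coded patient = 1, so a negative coefficient (and Cohen's d) means
    lower values in patients. Cohen's d is the covariate-adjusted group
    difference divided by the residual SD of the model.
    """
    control_maps = np.atleast_2d(np.asarray(control_maps, dtype=float))
    patient_maps = np.atleast_2d(np.asarray(patient_maps, dtype=float))
    n_c, n_p = control_maps.shape[0], patient_maps.shape[0]
    if min(n_c, n_p) < 5:
        raise ValueError("each group needs at least 5 subjects")
    y = np.vstack([control_maps, patient_maps])
    group = np.concatenate([np.zeros(n_c), np.ones(n_p)])
    sex_num = np.asarray(
        [1.0 if s in ("M", 1, True) else 0.0 for s in np.asarray(sex).ravel()]
    )
    x = np.column_stack([np.ones(n_c + n_p), group, np.asarray(age, float), sex_num])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient design matrix (collinear covariates)")

    n, k = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y  # (k, N)
    resid = y - x @ beta
    dof = n - k
    mse = (resid**2).sum(axis=0) / dof
    se_g = np.sqrt(mse * xtx_inv[1, 1])
    t = beta[1] / se_g
    p = 2 * stats.t.sf(np.abs(t), dof)
    q, rej = _bh(p, alpha)
    d = beta[1] / np.sqrt(mse)
    return GroupComparison(
        t=t, p=p, q=q, cohens_d=d, significant=rej, alpha=alpha,
        covariates=("age", "sex"),
    )


def summary_ttest(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, float]:
    """Two-sample t from summary statistics (Welch form).

    Equals the pooled-variance t when n1 = n2. Returns (t, two-sided p)
    with Welch-Satterthwaite degrees of freedom.
    """
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    v1, v2 = s1**2 / n1, s2**2 / n2
    t = (m1 - m2) / np.sqrt(v1 + v2)
    dof = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), dof)
    return float(t), float(p)


def chisq_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("need a nonnegative 2x2 table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def partial_corr(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    alternative: str = "two-sided",
) -> tuple[float, float, float]:
    """Partial correlation of x and y given covariates.

    Both variables are residualized on the covariates (plus intercept);
    the Pearson correlation of the residuals is tested with n - k - 2
    degrees of freedom. With no covariates this is the plain Pearson r.
    ``alternative`` may be "two-sided", "less" or "greater" (directional
    tests are used where a negative clinical effect is hypothesized).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        z = np.ones((n, 1))
        k = 0
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        z = np.column_stack([np.ones(n), cov])
        k = z.shape[1] - 1
    if n <= k + 2:
        raise ValueError("need n > k + 2 observations")
    rx = x - z @ np.linalg.lstsq(z, x, rcond=None)[0]
    ry = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("constant residuals; partial correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    dof = n - k - 2
    r_ = np.clip(r, -0.9999999999, 0.9999999999)
    t = r_ * np.sqrt(dof / (1 - r_**2))
    if alternative == "two-sided":
        p = 2 * stats.t.sf(abs(t), dof)
    elif alternative == "less":
        p = stats.t.cdf(t, dof)
    elif alternative == "greater":
        p = stats.t.sf(t, dof)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return r, float(t), float(p)


def network_means(
    control_maps: np.ndarray,
    patient_maps: np.ndarray,
    community: np.ndarray,
    alpha: float = 0.05,
) -> dict:
    """Per-community subject means compared between groups with BH-FDR.

    Returns per-community mean values by group, two-sample t statistics,
    p-values and BH q-values across communities.
    """
    control_maps = np.atleast_2d(np.asarray(control_maps, dtype=float))
    patient_maps = np.atleast_2d(np.asarray(patient_maps, dtype=float))
    community = np.asarray(community)
    labels = np.unique(community)
    t_vals, p_vals, mc, mp = [], [], [], []
    for lab in labels:
        mask = community == lab
        if not mask.any():
            raise ValueError(f"empty community {lab}")
        c = control_maps[:, mask].mean(axis=1)
        p_ = patient_maps[:, mask].mean(axis=1)
        t, p = stats.ttest_ind(p_, c)
        t_vals.append(float(t))
        p_vals.append(float(p))
        mc.append(float(c.mean()))
        mp.append(float(p_.mean()))
    q, rej = _bh(np.array(p_vals), alpha)
    return {
        "community": labels,
        "mean_control": np.array(mc),
        "mean_patient": np.array(mp),
        "t": np.array(t_vals),
        "p": np.array(p_vals),
        "q": q,
        "significant": rej,
    }


def pc1_scores(score_matrix: np.ndarray) -> tuple[np.ndarray, float]:
    """First-principal-component scores of a subjects x measures matrix.

    Columns are standardized before the SVD; the component sign is chosen
    so scores correlate positively with the column-mean composite (the
    conventional "higher = better overall performance" orientation).
    Returns (scores, variance_explained).
    """
    m = np.asarray(score_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    sd = m.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if len(bad):
        raise ValueError(f"zero-variance column(s) {bad.tolist()}")
    zs = (m - m.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(zs, full_matrices=False)
    scores = u[:, 0] * s[0]
    composite = zs.mean(axis=1)
    if np.corrcoef(scores, composite)[0, 1] < 0:
        scores = -scores
    var_exp = float(s[0] ** 2 / np.sum(s**2))
    return scores, var_exp
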