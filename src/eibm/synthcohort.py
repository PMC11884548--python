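"""Synthetic cohort generation.

Builds the full data substrate of a case-control resting-state study:
a two-hemisphere spherical parcellation with homotopic region pairs, a
distance-dependent structural connectome, smooth cortical annotation maps
(myelin proxy and connectivity gradient), and per-subject region-wise
fractional Gaussian noise (fGn) time series whose Hurst exponents encode a
known group difference. Patients carry a reduced Hurst exponent (i.e., a
shifted E/I balance) in a designated set of regions on the seizure-focus
hemisphere; controls sit at baseline. Ground truth is recorded so that
downstream sensitivity/specificity can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform, pdist
from sklearn.cluster import KMeans

__all__ = [
    "Parcellation",
    "Connectome",
    "SubjectRecord",
    "Cohort",
    "CohortSpec",
    "make_geometry",
    "make_connectome",
    "make_annotation_maps",
    "simulate_fgn",
    "make_cohort",
    "fgn_autocovariance",
]


@dataclass
class Parcellation:
    """Region geometry: unit-sphere centroids, hemisphere labels, communities.

    Regions ``0 .. N/2-1`` are left-hemisphere (x < 0) and region
    ``i + N/2`` is the homotopic right-hemisphere mirror of region ``i``.
    """

    centroids: np.ndarray  # (N, 3), unit norm
    hemisphere: np.ndarray  # (N,) of "L"/"R"
    community: np.ndarray  # (N,) integer labels

    @property
    def n_regions(self) -> int:
        return len(self.hemisphere)

    def homotopic_pair(self, i: int) -> int:
        """Index of the mirror region in the opposite hemisphere."""
        half = self.n_regions // 2
        return i + half if i < half else i - half


@dataclass
class Connectome:
    """Symmetric structural connectivity, centroid distances, optional FC."""

    sc: np.ndarray
    dist: np.ndarray
    fc: np.ndarray | None = None


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # "control" | "patient"
    focus_side: str  # "L" | "R" | "none"
    age: float
    sex: str  # "M" | "F"
    ts: np.ndarray  # (T, N)
    cognition: dict[str, float] = field(default_factory=dict)


@dataclass
class Cohort:
    parcellation: Parcellation
    connectome: Connectome
    subjects: list[SubjectRecord]
    truth: dict | None = None

    @property
    def controls(self) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == "control"]

    @property
    def patients(self) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == "patient"]


def make_geometry(n_regions: int, n_communities: int = 4, seed: int | None = None) -> Parcellation:
    """Sample a mirrored two-hemisphere parcellation on the unit sphere.

    Each hemisphere's centroids cover a full unit sphere (as on a
    per-hemisphere spherical surface projection): left-hemisphere
    centroids are drawn uniformly and reflected through the x = 0 plane
    to create homotopic right-hemisphere twins. Full-sphere coverage per
    hemisphere is what makes rotation-based (spin) surrogates
    well-calibrated — rotating a half-sphere point cloud would leave
    coverage gaps and distort reassigned maps. Communities are spatial
    k-means clusters of the midline-folded coordinates ``(|x|, y, z)`` so
    each community is bilateral, as functional networks are.
    """
    if n_regions % 2 != 0:
        raise ValueError(f"n_regions must be even, got {n_regions}")
    if n_regions < 8:
        raise ValueError(f"n_regions must be >= 8, got {n_regions}")
    if n_communities < 1:
        raise ValueError("n_communities must be >= 1")
    rng = np.random.default_rng(seed)
    half = n_regions // 2
    pts = rng.standard_normal((half, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    mirrored = pts.copy()
    mirrored[:, 0] *= -1
    centroids = np.vstack([pts, mirrored])
    hemisphere = np.array(["L"] * half + ["R"] * half)

    folded = centroids.copy()
    folded[:, 0] = np.abs(folded[:, 0])
    km = KMeans(n_clusters=n_communities, n_init=10, random_state=int(rng.integers(2**31)))
    community = km.fit_predict(folded)
    return Parcellation(centroids=centroids, hemisphere=hemisphere, community=community)


def make_connectome(
    parc: Parcellation,
    density: float = 0.3,
    decay_length: float = 0.7,
    seed: int | None = None,
) -> Connectome:
    """Distance-dependent random structural connectome.

    Edge existence probability decays as ``exp(-dist / decay_length)``;
    weights are log-normal; the minimum spanning tree over centroid distance
    is always included so the graph is connected. Realized edge count is
    calibrated to the requested density in expectation.
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    if decay_length <= 0:
        raise ValueError("decay_length must be positive")
    rng = np.random.default_rng(seed)
    n = parc.n_regions
    dist = squareform(pdist(parc.centroids))
    n_pairs = n * (n - 1) // 2
    n_target = int(round(density * n_pairs))
    if n_target < n - 1:
        raise ValueError(
            f"density {density} gives {n_target} edges; {n - 1} needed for a "
            f"connected graph on {n} regions"
        )

    iu = np.triu_indices(n, 1)
    adj = np.zeros((n, n), dtype=bool)
    if density == 1.0:
        adj[iu] = True
    else:
        mst = minimum_spanning_tree(dist).toarray()
        mst_mask = (mst + mst.T) > 0
        adj |= np.triu(mst_mask, 1)
        n_mst = int(adj.sum())
        # scale the decay kernel so the expected extra-edge count hits target
        free = np.triu(~mst_mask, 1)
        kernel = np.exp(-dist / decay_length)
        scale = (n_target - n_mst) / kernel[free].sum()
        prob = np.clip(scale * kernel, 0, 1)
        draw = rng.random((n, n)) < prob
        adj |= np.triu(draw & free, 1)

    weights = rng.lognormal(mean=0.0, sigma=0.5, size=(n, n))
    sc = np.zeros((n, n))
    sc[adj] = weights[adj]
    sc = sc + sc.T
    np.fill_diagonal(sc, 0.0)
    return Connectome(sc=sc, dist=dist)


def _real_sph_harm_basis(centroids: np.ndarray, l_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Real spherical-harmonic design matrix and the order of each column.

    Columns are orthonormal real harmonics Y_lm, l = 1..l_max, evaluated
    at the centroid directions; iid coefficients within each order give a
    rotation-isotropic Gaussian random field.
    """
    from scipy.special import sph_harm_y

    x, y, z = centroids.T
    theta = np.arccos(np.clip(z, -1, 1))  # polar
    phi = np.arctan2(y, x)  # azimuth
    cols, orders = [], []
    for l in range(1, l_max + 1):
        ylm = sph_harm_y(l, np.arange(0, l + 1)[:, None], theta[None, :], phi[None, :])
        cols.append(ylm[0].real)  # m = 0
        orders.append(l)
        for m in range(1, l + 1):
            cols.append(np.sqrt(2) * (-1) ** m * ylm[m].real)
            cols.append(np.sqrt(2) * (-1) ** m * ylm[m].imag)
            orders.extend([l, l])
    return np.array(cols).T, np.array(orders)


def make_annotation_maps(
    parc: Parcellation,
    smoothness: float = 5.0,
    l_max: int = 4,
    homotopic_rho: float = 0.7,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth z-scored annotation maps (myelin proxy, FC gradient proxy).

    Each hemisphere is treated as its own spherical surface (as in
    surface-based neuroimaging): the left-hemisphere values are an
    isotropic Gaussian random field built from real spherical harmonics
    of orders 1..``l_max`` with a 1/l amplitude decay plus white noise of
    amplitude ``1/smoothness``; the right hemisphere is a noisy copy with
    homotopic correlation ``homotopic_rho``, mirroring the rough
    bilateral symmetry of real cortical annotations. Maps are z-scored
    across regions. The per-hemisphere isotropy makes rotation (spin)
    surrogates exchangeable with the original maps.
    """
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    if not 0 <= homotopic_rho <= 1:
        raise ValueError("homotopic_rho must be in [0, 1]")
    rng = np.random.default_rng(seed)
    half = parc.n_regions // 2
    basis, orders = _real_sph_harm_basis(parc.centroids[:half], l_max)
    amp = 1.0 / orders  # red spatial spectrum

    def hemi_field() -> np.ndarray:
        coef = amp * rng.standard_normal(basis.shape[1])
        m = basis @ coef
        m /= m.std()
        m = m + rng.normal(0.0, 1.0 / smoothness, size=half)
        return (m - m.mean()) / m.std()

    def one_map() -> np.ndarray:
        left = hemi_field()
        right = homotopic_rho * left + np.sqrt(1 - homotopic_rho**2) * hemi_field()
        m = np.concatenate([left, right])
        return (m - m.mean()) / m.std()

    return one_map(), one_map()


def fgn_autocovariance(H: float, max_lag: int, sigma2: float = 1.0) -> np.ndarray:
    """Autocovariance gamma(k) of fGn for lags 0..max_lag."""
    k = np.arange(max_lag + 1, dtype=float)
    return sigma2 / 2.0 * (
        np.abs(k + 1) ** (2 * H) - 2 * np.abs(k) ** (2 * H) + np.abs(k - 1) ** (2 * H)
    )


def simulate_fgn(
    H: float, n_samples: int, sigma2: float = 1.0, seed: int | None = None
) -> np.ndarray:
    """Exact stationary fractional Gaussian noise via circulant embedding.

    Davies-Harte synthesis: the target autocovariance is embedded in a
    circulant matrix whose eigenvalues (FFT of the first row) are provably
    nonnegative for the fGn autocovariance, so the sample path has exactly
    the target second-order structure. Lengths that are not powers of two
    are padded to the next power of two and truncated, keeping the
    embedding exact.
    """
    if not 0 < H < 1:
        raise ValueError(f"H must be in (0, 1), got {H}")
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    m = 1 << max(1, (n_samples - 1).bit_length())  # next power of two
    gamma = fgn_autocovariance(H, m, sigma2)
    # circulant first row: gamma(0..m), gamma(m-1..1)
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(row).real
    assert lam.min() > -1e-8 * lam.max(), "circulant embedding not nonnegative"
    lam = np.clip(lam, 0.0, None)

    two_m = 2 * m
    w = np.empty(two_m, dtype=complex)
    u = rng.standard_normal(m + 1)
    v = rng.standard_normal(m - 1)
    w[0] = np.sqrt(lam[0]) * u[0]
    w[m] = np.sqrt(lam[m]) * u[m]
    half = np.sqrt(lam[1:m] / 2.0)
    w[1:m] = half * (u[1:m] + 1j * v)
    w[m + 1 :] = np.conj(w[m - 1 : 0 : -1])
    x = np.fft.fft(w) / np.sqrt(two_m)
    return x.real[:n_samples]


@dataclass
class CohortSpec:
    """Generating parameters for a synthetic case-control cohort.

    ``affected_regions`` are region indices interpreted in the ipsilateral
    (left-focus) frame: a right-focus patient expresses the effect in the
    homotopic counterparts instead. ``delta_h`` > 0 is the Hurst decrease in
    affected regions of patients (lower H = higher E/I ratio).
    ``homotopic_fraction`` optionally applies a milder (scaled) effect to
    the homotopic twins of affected regions on the contralateral side.
    ``cognition_slope`` couples the cognitive score to the subject's mean
    true Hurst exponent: score = slope * mean(H) + N(0, cognition_noise_sd).
    """

    n_controls: int = 40
    n_patients: int = 40
    n_regions: int = 68
    n_timepoints: int = 1024
    baseline_h: float | np.ndarray = 0.7
    affected_regions: tuple[int, ...] = ()
    delta_h: float = 0.1
    homotopic_fraction: float = 0.0
    subject_h_sd: float = 0.0
    focus_side: str = "random"  # "random" | "L" | "R"
    age_range: tuple[float, float] = (20.0, 60.0)
    cognition_slope: float = 0.0
    cognition_noise_sd: float = 1.0
    n_communities: int = 4
    sc_density: float = 0.3
    sc_decay_length: float = 0.7


def _patient_h_map(base: np.ndarray, spec: CohortSpec, focus: str, half: int) -> np.ndarray:
    h = base.copy()
    affected = np.asarray(spec.affected_regions, dtype=int)
    if focus == "R" and len(affected):
        affected = np.where(affected < half, affected + half, affected - half)
    h[affected] -= spec.delta_h
    if spec.homotopic_fraction > 0 and len(affected):
        homo = np.where(affected < half, affected + half, affected - half)
        h[homo] -= spec.homotopic_fraction * spec.delta_h
    return h


def make_cohort(spec: CohortSpec, seed: int | None = None) -> Cohort:
    """Generate a full synthetic cohort with recorded ground truth.

    Controls draw region-wise fGn at the baseline Hurst map; patients draw
    fGn with H reduced by ``delta_h`` in the affected regions of their focus
    hemisphere. Regions are independent processes (Hurst estimation is
    per-region), covariates are sampled without group confounding, and the
    generating parameters are stored in ``Cohort.truth``.
    """
    n = spec.n_regions
    base = np.broadcast_to(np.asarray(spec.baseline_h, dtype=float), (n,)).copy()
    affected = np.asarray(spec.affected_regions, dtype=int)
    if len(affected) and (affected.min() < 0 or affected.max() >= n):
        raise ValueError(f"affected_regions must lie in [0, {n})")
    rng = np.random.default_rng(seed)
    half = n // 2

    parc = make_geometry(n, spec.n_communities, seed=int(rng.integers(2**31)))
    conn = make_connectome(
        parc, spec.sc_density, spec.sc_decay_length, seed=int(rng.integers(2**31))
    )

    subjects: list[SubjectRecord] = []
    groups = ["control"] * spec.n_controls + ["patient"] * spec.n_patients
    focus_sides: list[str] = []
    for idx, group in enumerate(groups):
        if group == "control":
            focus = "none"
            h_map = base.copy()
        else:
            if spec.focus_side == "random":
                focus = "L" if rng.random() < 0.5 else "R"
            else:
                focus = spec.focus_side
            h_map = _patient_h_map(base, spec, focus, half)
        focus_sides.append(focus)
        if spec.subject_h_sd > 0:
            h_map = np.clip(
                h_map + rng.normal(0.0, spec.subject_h_sd, size=n), 0.05, 0.95
            )
        ts = np.column_stack(
            [
                simulate_fgn(h_map[r], spec.n_timepoints, seed=int(rng.integers(2**31)))
                for r in range(n)
            ]
        )
        age = rng.uniform(*spec.age_range)
        sex = "M" if rng.random() < 0.5 else "F"
        score = spec.cognition_slope * h_map.mean() + rng.normal(
            0.0, spec.cognition_noise_sd
        )
        subjects.append(
            SubjectRecord(
                subject_id=f"sub-{idx:03d}",
                group=group,
                focus_side=focus,
                age=age,
                sex=sex,
                ts=ts,
                cognition={"score": score},
            )
        )

    truth = {
        "h_control": base,
        "h_patient_ipsi": _patient_h_map(base, spec, "L", half),
        "affected_regions": affected,
        "delta_h": spec.delta_h,
        "focus_sides": focus_sides,
        "spec": spec,
    }
    return Cohort(parcellation=parc, connectome=conn, subjects=subjects, truth=truth)
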