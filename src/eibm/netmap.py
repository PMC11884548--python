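"""Network spreading statistics, epicenter mapping, and null models.

A region-wise alteration map (typically Cohen's d of the Hurst exponent)
is related to network architecture in two ways. Neighbor alteration asks
whether a node's alteration tracks the average alteration of its
structurally connected neighbors,

    D_i = (1/N_i) * sum_{j != i, SC_ij > 0} d_j * SC_ij            (SC)
    D_i = (1/N_i) * sum_{j != i, SC_ij > 0} d_j * SC_ij * FC_ij    (SC & FC)

with N_i the node degree. Epicenter mapping correlates each region's
healthy connectivity profile with the whole-brain alteration map; highly
ranked regions are candidate origins of network-spread pathology.

Two null models guard the inference: spin surrogates (random rotations of
the spherical region coordinates, preserving spatial autocorrelation) and
geometry-preserving rewired connectomes (within-distance-bin double-edge
swaps preserving the degree sequence and binned edge-length distribution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import stats
from scipy.stats import special_ortho_group

from eibm.synthcohort import Parcellation

__all__ = [
    "NullDistribution",
    "neighbor_alteration",
    "node_neighbor_coupling",
    "epicenter_likelihood",
    "spin_surrogates",
    "spin_pvalue",
    "rewire_preserving_length",
    "rewired_pvalue",
    "morans_i",
]

logger = logging.getLogger(__name__)


@dataclass
class NullDistribution:
    """Observed statistic against a surrogate ensemble."""

    observed: float
    surrogates: np.ndarray
    p_value: float
    null_type: str  # "spin" | "rewired" | "label-permutation"
    alternative: str


def neighbor_alteration(
    d_map: np.ndarray, sc: np.ndarray, fc: np.ndarray | None = None
) -> np.ndarray:
    """Mean weighted alteration of each node's structural neighbors.

    Neighbors are the regions with a nonzero structural connection;
    the normalizer is the neighbor count (node degree), not the weight
    sum. With ``fc`` given, each term is additionally weighted by the
    functional connectivity to the node. Isolated nodes get NaN.
    """
    d_map = np.asarray(d_map, dtype=float)
    sc = np.asarray(sc, dtype=float)
    n = len(d_map)
    if sc.shape != (n, n):
        raise ValueError("SC shape does not match map length")
    if not np.allclose(sc, sc.T):
        raise ValueError("SC must be symmetric")
    if np.any(sc < 0):
        raise ValueError("SC must be nonnegative")
    if not sc.any():
        raise ValueError("SC is all-zero")
    w = sc.copy()
    np.fill_diagonal(w, 0.0)
    if fc is not None:
        fc = np.asarray(fc, dtype=float)
        if fc.shape != sc.shape:
            raise ValueError("FC shape does not match SC")
        w = w * fc
    mask = sc > 0
    np.fill_diagonal(mask, False)
    degree = mask.sum(axis=1)
    out = np.full(n, np.nan)
    nz = degree > 0
    vals = (w * mask) @ d_map / np.where(nz, degree, 1)
    out[nz] = vals[nz]
    if (~nz).any():
        logger.warning("isolated node(s) %s set to NaN", np.flatnonzero(~nz).tolist())
    return out


def node_neighbor_coupling(
    d_map: np.ndarray, sc: np.ndarray, fc: np.ndarray | None = None
) -> float:
    """Spearman correlation between node alteration and neighbor alteration."""
    nb = neighbor_alteration(d_map, sc, fc)
    ok = np.isfinite(nb) & np.isfinite(d_map)
    return float(stats.spearmanr(np.asarray(d_map)[ok], nb[ok]).statistic)


def epicenter_likelihood(
    d_map: np.ndarray,
    profile_matrix: np.ndarray,
    parc: Parcellation | None = None,
    n_spin: int = 0,
    seed: int | None = None,
) -> dict:
    """Epicenter likelihood: profile-to-alteration spatial correlation.

    For each region i, the Spearman correlation between its connectivity
    profile (row i with the self-entry removed) and the alteration map
    (entry i removed). Likelihoods are ranked in descending order (rank 1
    = most likely epicenter). With ``n_spin`` > 0 and a parcellation,
    per-region spin p-values are computed by rotating the alteration map.
    """
    d_map = np.asarray(d_map, dtype=float)
    prof = np.asarray(profile_matrix, dtype=float)
    n = len(d_map)
    if prof.shape != (n, n):
        raise ValueError("profile matrix shape does not match map")

    def likelihoods(d: np.ndarray) -> np.ndarray:
        out = np.full(n, np.nan)
        for i in range(n):
            row = np.delete(prof[i], i)
            di = np.delete(d, i)
            if np.ptp(row) == 0:
                continue
            out[i] = stats.spearmanr(row, di).statistic
        return out

    like = likelihoods(d_map)
    order = np.argsort(np.where(np.isfinite(like), -like, np.inf), kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)

    p_spin = None
    if n_spin > 0:
        if parc is None:
            raise ValueError("spin p-values require a parcellation")
        surr = spin_surrogates(d_map, parc, n_spin, seed=seed)
        null = np.array([likelihoods(s) for s in surr])
        exceed = np.sum(np.abs(null) >= np.abs(like)[None, :], axis=0)
        p_spin = (1.0 + exceed) / (n_spin + 1.0)
    return {"likelihood": like, "rank": ranks, "p_spin": p_spin}


def _rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    return special_ortho_group.rvs(3, size=n, random_state=rng).reshape(n, 3, 3)


def spin_surrogates(
    map_values: np.ndarray,
    parc: Parcellation,
    n_rotations: int,
    seed: int | None = None,
) -> np.ndarray:
    """Spatial-autocorrelation-preserving surrogate maps by rotation.

    Each iteration draws a uniform random 3-D rotation, applies it to the
    left-hemisphere centroids and its x-mirrored counterpart to the right,
    and reassigns every region the value of the nearest rotated source
    region within its own hemisphere (so no left value lands in a right
    slot). Returns an (n_rotations, N) array.
    """
    map_values = np.asarray(map_values, dtype=float)
    n = parc.n_regions
    half = n // 2
    c_l = parc.centroids[:half]
    c_r = parc.centroids[half:]
    rng = np.random.default_rng(seed)
    rots = _rotations(n_rotations, rng)
    mirror = np.diag([-1.0, 1.0, 1.0])
    rots_r = mirror @ rots @ mirror

    out = np.empty((n_rotations, n))
    for centroids, rot_set, sl in (
        (c_l, rots, slice(0, half)),
        (c_r, rots_r, slice(half, n)),
    ):
        rotated = np.einsum("nij,sj->nsi", rot_set, centroids)  # (n_rot, src, 3)
        # nearest on the unit sphere = largest dot product
        sim = np.einsum("ti,nsi->nts", centroids, rotated)
        src = np.argmax(sim, axis=2)  # (n_rot, targets)
        out[:, sl] = map_values[sl][src]
    return out


def spin_pvalue(
    stat_fn,
    map_a: np.ndarray,
    map_b: np.ndarray,
    parc: Parcellation,
    n: int = 5000,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> NullDistribution:
    """Spin-test p-value for a statistic of two cortical maps.

    The first map is rotated; the second stays fixed. Two-sided by
    default, with the standard +1 permutation correction.
    """
    observed = float(stat_fn(map_a, map_b))
    surr = spin_surrogates(map_a, parc, n, seed=seed)
    null = np.array([stat_fn(s, map_b) for s in surr])
    if alternative == "two-sided":
        exceed = np.sum(np.abs(null) >= np.abs(observed))
    elif alternative == "greater":
        exceed = np.sum(null >= observed)
    elif alternative == "less":
        exceed = np.sum(null <= observed)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (1.0 + exceed) / (n + 1.0)
    return NullDistribution(observed, null, float(p), "spin", alternative)


def rewire_preserving_length(
    sc: np.ndarray,
    dist: np.ndarray,
    n_bins: int = 10,
    n_swap_passes: int = 10,
    seed: int | None = None,
) -> np.ndarray:
    """Degree- and binned-length-preserving rewired surrogate connectome.

    Edges are binned by Euclidean distance into equal-count bins; within
    each bin, Maslov-Sneppen double-edge swaps ((a,b),(c,d) -> (a,d),(c,b))
    are attempted ``n_swap_passes`` times the edge count, accepted only
    when no self- or duplicate edge would arise and both replacement
    edges fall within one bin of the pair they replace (strict same-bin
    acceptance mixes too slowly on sparse desk-scale graphs). Weights
    travel with the swapped edges. The degree sequence is preserved
    exactly and the binned edge-length distribution almost exactly.
    """
    sc = np.asarray(sc, dtype=float)
    if not np.allclose(sc, sc.T):
        raise ValueError("SC must be symmetric")
    n = sc.shape[0]
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, 1)
    present = sc[iu, ju] > 0
    edges = np.column_stack([iu[present], ju[present]])
    weights = sc[iu, ju][present]
    lengths = dist[iu, ju][present]
    m = len(edges)
    qs = np.quantile(lengths, np.linspace(0, 1, n_bins + 1))
    bin_of = np.clip(np.searchsorted(qs, lengths, side="right") - 1, 0, n_bins - 1)

    edges = edges.astype(np.int64)
    adj = np.zeros((n, n), dtype=np.bool_)
    adj[edges[:, 0], edges[:, 1]] = True
    adj[edges[:, 1], edges[:, 0]] = True
    pair_bin = np.clip(
        np.searchsorted(qs, dist, side="right") - 1, 0, n_bins - 1
    ).astype(np.int64)
    _swap_within_bins(
        edges, bin_of.astype(np.int64), pair_bin, n_bins, n_swap_passes, adj,
        int(rng.integers(2**31)),
    )
    out = np.zeros_like(sc)
    out[edges[:, 0], edges[:, 1]] = weights
    out[edges[:, 1], edges[:, 0]] = weights
    return out


@njit(cache=True)
def _swap_within_bins(edges, bin_of, pair_bin, n_bins, n_swap_passes, adj,
                      seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    for b in range(n_bins):
        idx = np.where(bin_of == b)[0]
        m = len(idx)
        if m < 2:
            continue
        for _ in range(n_swap_passes * m):
            p1 = idx[np.random.randint(m)]
            p2 = idx[np.random.randint(m)]
            if p1 == p2:
                continue
            a, b1 = edges[p1, 0], edges[p1, 1]
            c, d = edges[p2, 0], edges[p2, 1]
            if np.random.random() < 0.5:
                a, b1 = b1, a
            if np.random.random() < 0.5:
                c, d = d, c
            if a == c or a == d or b1 == c or b1 == d:
                continue
            if adj[a, d] or adj[c, b1]:
                continue
            if abs(pair_bin[a, d] - b) > 1 or abs(pair_bin[c, b1] - b) > 1:
                continue
            adj[a, b1] = adj[b1, a] = False
            adj[c, d] = adj[d, c] = False
            adj[a, d] = adj[d, a] = True
            adj[c, b1] = adj[b1, c] = True
            edges[p1, 0], edges[p1, 1] = a, d
            edges[p2, 0], edges[p2, 1] = c, b1


def rewired_pvalue(
    stat_fn,
    d_map: np.ndarray,
    sc: np.ndarray,
    dist: np.ndarray,
    n_null: int = 1000,
    n_bins: int = 10,
    n_swap_passes: int = 10,
    seed: int | None = None,
) -> NullDistribution:
    """One-sided rewired-null p: fraction of surrogate statistics that
    exceed the observed (with +1 correction)."""
    observed = float(stat_fn(d_map, sc))
    rng = np.random.default_rng(seed)
    null = np.empty(n_null)
    for i in range(n_null):
        surr = rewire_preserving_length(
            sc, dist, n_bins, n_swap_passes, seed=int(rng.integers(2**31))
        )
        null[i] = stat_fn(d_map, surr)
    p = (1.0 + np.sum(null >= observed)) / (n_null + 1.0)
    return NullDistribution(observed, null, float(p), "rewired", "greater")


def morans_i(values: np.ndarray, weight: np.ndarray) -> float:
    """Moran's I spatial autocorrelation under a weight matrix."""
    x = np.asarray(values, dtype=float)
    w = np.asarray(weight, dtype=float).copy()
    np.fill_diagonal(w, 0.0)
    z = x - x.mean()
    denom = np.sum(z**2)
    if denom == 0:
        return 0.0
    return float(len(x) / w.sum() * (z @ w @ z) / denom)
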