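"""Static and dynamic functional connectivity.

Static FC is the Pearson correlation of region pairs over the full scan.
Functional connectivity dynamics (FCD) captures time-varying network
states: FC is recomputed in overlapping sliding windows, each windowed FC
upper triangle is vectorized, and the vectors are pairwise correlated into
a W x W similarity matrix. The distribution of FCD entries (its empirical
CDF) and the Kolmogorov-Smirnov distance between such distributions form
the dynamic half of the mean-field model fitting cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FCDMatrix",
    "EmpiricalCDF",
    "static_fc",
    "sliding_window_fcd",
    "fcd_cdf",
    "group_fc",
    "group_fcd_cdf",
    "ks_distance",
]


@dataclass
class FCDMatrix:
    values: np.ndarray  # (W, W) correlations between windowed FC patterns
    window_length: int
    step: int


@dataclass
class EmpiricalCDF:
    """Right-continuous step (or grid-averaged) CDF."""

    grid: np.ndarray  # sorted support points
    cum: np.ndarray  # cumulative probability at each grid point

    @classmethod
    def from_samples(cls, samples: np.ndarray) -> "EmpiricalCDF":
        grid = np.sort(np.asarray(samples, dtype=float))
        n = len(grid)
        return cls(grid=grid, cum=np.arange(1, n + 1) / n)

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """CDF value at x: step interpolation, 0 left of support."""
        idx = np.searchsorted(self.grid, np.asarray(x, dtype=float), side="right")
        cum = np.concatenate([[0.0], self.cum])
        return cum[idx]

    @property
    def median(self) -> float:
        return float(self.grid[np.searchsorted(self.cum, 0.5)])


def _check_columns(ts: np.ndarray) -> None:
    sd = ts.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if len(bad):
        raise ValueError(f"constant time series in region(s) {bad.tolist()}")


def static_fc(ts: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of a T x N time-series matrix."""
    ts = np.asarray(ts, dtype=float)
    if ts.shape[0] < 2:
        raise ValueError("need at least 2 time points")
    _check_columns(ts)
    fc = np.corrcoef(ts, rowvar=False)
    fc = np.clip((fc + fc.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(fc, 1.0)
    return fc


def _windowed_fc_vectors(ts: np.ndarray, window_length: int, step: int) -> np.ndarray:
    """Upper-triangle FC vectors of all sliding windows, via cumulative sums."""
    t, n = ts.shape
    iu, ju = np.triu_indices(n, 1)
    starts = np.arange(0, t - window_length + 1, step)

    z = np.zeros((1, n))
    cs = np.vstack([z, np.cumsum(ts, axis=0)])
    cs2 = np.vstack([z, np.cumsum(ts**2, axis=0)])
    prod = ts[:, iu] * ts[:, ju]
    csp = np.vstack([np.zeros((1, len(iu))), np.cumsum(prod, axis=0)])

    w = window_length
    sx = cs[starts + w] - cs[starts]
    sx2 = cs2[starts + w] - cs2[starts]
    sxy = csp[starts + w] - csp[starts]
    var = w * sx2 - sx**2
    num = w * sxy - sx[:, iu] * sx[:, ju]
    den = np.sqrt(var[:, iu] * var[:, ju])
    with np.errstate(invalid="ignore", divide="ignore"):
        vecs = num / den
    return np.clip(vecs, -1.0, 1.0)


def sliding_window_fcd(ts: np.ndarray, window_length: int = 100, step: int = 1) -> FCDMatrix:
    """FCD matrix: correlations between vectorized sliding-window FCs.

    With step 1 the window count is W = T - window_length + 1 (e.g. a
    695-sample scan with 100-sample windows yields a 596 x 596 matrix).
    """
    ts = np.asarray(ts, dtype=float)
    t = ts.shape[0]
    if t < window_length + 1:
        raise ValueError(
            f"series length {t} must exceed window_length {window_length}"
        )
    _check_columns(ts)
    vecs = _windowed_fc_vectors(ts, window_length, step)
    fcd = np.corrcoef(vecs)
    fcd = np.clip((fcd + fcd.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(fcd, 1.0)
    return FCDMatrix(values=fcd, window_length=window_length, step=step)


def fcd_cdf(fcd: FCDMatrix) -> EmpiricalCDF:
    """Empirical CDF of the FCD upper-triangle entries."""
    v = fcd.values
    if v.shape[0] < 2:
        raise ValueError("FCD matrix must be at least 2 x 2")
    iu = np.triu_indices(v.shape[0], 1)
    return EmpiricalCDF.from_samples(v[iu])


def group_fc(fc_list: list[np.ndarray]) -> np.ndarray:
    """Group-average FC: Fisher z-transform, mean, back-transform."""
    if not fc_list:
        raise ValueError("empty FC list")
    shape = fc_list[0].shape
    if any(fc.shape != shape for fc in fc_list):
        raise ValueError("FC matrices have mismatched dimensions")
    z = np.mean([np.arctanh(np.clip(fc, -0.999999, 0.999999)) for fc in fc_list], axis=0)
    out = np.tanh(z)
    np.fill_diagonal(out, 1.0)
    return out


def group_fcd_cdf(cdf_list: list[EmpiricalCDF], n_grid: int = 1000) -> EmpiricalCDF:
    """Pointwise average of CDFs on a common grid over [-1, 1]."""
    if not cdf_list:
        raise ValueError("empty CDF list")
    grid = np.linspace(-1.0, 1.0, n_grid)
    cum = np.mean([c.evaluate(grid) for c in cdf_list], axis=0)
    cum[-1] = 1.0
    return EmpiricalCDF(grid=grid, cum=cum)


def ks_distance(cdf_a: EmpiricalCDF, cdf_b: EmpiricalCDF) -> float:
    """Sup-norm distance between two CDFs on the union of their grids."""
    grid = np.union1d(cdf_a.grid, cdf_b.grid)
    return float(np.max(np.abs(cdf_a.evaluate(grid) - cdf_b.evaluate(grid))))
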