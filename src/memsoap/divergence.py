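"""Distributional comparison of spectrum ensembles.

Instead of collapsing each ensemble to a single mean spectrum, this path
compares the *distributions* of per-lipid spectra: subsample spectra per
frame, project everything into a shared low-dimensional PCA basis, estimate
each system's probability density on a common grid, and measure the
Jensen-Shannon divergence between the gridded densities. The TwoNN intrinsic
dimension estimate justifies how few PCA components suffice.

The grid density uses a k-nearest-neighbor estimator at the sample points,
extrapolated to grid cells by an inverse-distance-weighted average over each
cell's three nearest sample points, then normalized to unit mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import gammaln
from scipy.stats import pearsonr, spearmanr

from .errors import IncompatibilityError, InsufficientDataError

__all__ = [
    "ReducedEnsemble",
    "GridSpec",
    "GriddedDensity",
    "subsample_spectra",
    "pca_reduce",
    "twonn_intrinsic_dimension",
    "knn_density_on_grid",
    "jensen_shannon",
    "correlate_metrics",
]


@dataclass
class ReducedEnsemble:
    """PCA scores of one system in a basis shared across systems."""

    points: np.ndarray
    basis: np.ndarray            # (k, D) principal axes
    mean: np.ndarray             # (D,) center of the pooled fit
    explained_variance: np.ndarray
    total_variance: float = 0.0  # sum over ALL principal axes
    source: str = ""

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        if self.total_variance <= 0:
            return np.zeros_like(self.explained_variance)
        return self.explained_variance / self.total_variance


@dataclass(frozen=True)
class GridSpec:
    """Regular rectangular grid: per-dimension (min, max, n_bins)."""

    mins: tuple[float, ...]
    maxs: tuple[float, ...]
    bins: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.mins) == len(self.maxs) == len(self.bins)):
            raise IncompatibilityError("grid axes must have equal length specs")
        if any(b < 2 for b in self.bins):
            raise IncompatibilityError("each grid axis needs >= 2 bins")
        if any(hi <= lo for lo, hi in zip(self.mins, self.maxs)):
            raise IncompatibilityError("grid max must exceed min on every axis")

    @property
    def ndim(self) -> int:
        return len(self.bins)

    def centers(self) -> list[np.ndarray]:
        out = []
        for lo, hi, b in zip(self.mins, self.maxs, self.bins):
            edges = np.linspace(lo, hi, b + 1)
            out.append(0.5 * (edges[:-1] + edges[1:]))
        return out

    def cell_centers(self) -> np.ndarray:
        axes = self.centers()
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=-1)

    @classmethod
    def from_data(cls, points: np.ndarray, bins: int = 12,
                  margin: float = 0.05) -> "GridSpec":
        points = np.asarray(points)
        lo, hi = points.min(axis=0), points.max(axis=0)
        pad = (hi - lo) * margin
        pad = np.where(pad > 0, pad, 1e-6)
        return cls(tuple(lo - pad), tuple(hi + pad),
                   tuple([bins] * points.shape[1]))


@dataclass
class GriddedDensity:
    """Probability mass over the cells of a :class:`GridSpec` (sums to 1)."""

    grid: GridSpec
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.mass = np.asarray(self.mass, dtype=np.float64)
        if self.mass.shape != tuple(self.grid.bins):
            raise IncompatibilityError(
                f"mass shape {self.mass.shape} does not match grid "
                f"{self.grid.bins}")
        if self.mass.min() < 0:
            raise IncompatibilityError("density mass must be non-negative")
        if abs(float(self.mass.sum()) - 1.0) > 1e-9:
            raise IncompatibilityError("density mass must sum to 1")


def subsample_spectra(per_frame: Sequence[np.ndarray], per_frame_count: int,
                      n_frames: int, seed: int) -> np.ndarray:
    """Uniform without-replacement sample of spectra: ``per_frame_count`` rows
    from each of ``n_frames`` frames (frames taken evenly spaced from the
    start), reproducible by seed. Returns (per_frame_count * n_frames, D).
    """
    if n_frames > len(per_frame):
        raise InsufficientDataError(
            f"requested {n_frames} frames, only {len(per_frame)} available")
    rng = np.random.default_rng(seed)
    frame_idx = np.linspace(0, len(per_frame) - 1, n_frames).round().astype(int)
    out = []
    for fi in frame_idx:
        arr = np.asarray(per_frame[fi])
        if per_frame_count > arr.shape[0]:
            raise InsufficientDataError(
                f"frame {fi} holds {arr.shape[0]} spectra, "
                f"requested {per_frame_count}")
        if per_frame_count == arr.shape[0]:
            out.append(arr)
        else:
            pick = rng.choice(arr.shape[0], size=per_frame_count, replace=False)
            out.append(arr[np.sort(pick)])
    return np.concatenate(out, axis=0)


def pca_reduce(samples: Mapping[str, np.ndarray] | np.ndarray,
               k: int) -> dict[str, ReducedEnsemble] | ReducedEnsemble:
    """Project one or several systems into the top-k PCA basis of the pooled
    sample (single shared basis), with a deterministic sign convention: the
    largest-magnitude loading of each axis is positive.
    """
    single = isinstance(samples, np.ndarray)
    named = {"sample": samples} if single else dict(samples)
    arrays = {n: np.asarray(v) for n, v in named.items()}
    n_total = sum(a.shape[0] for a in arrays.values())
    d = next(iter(arrays.values())).shape[1]
    if n_total <= k:
        raise InsufficientDataError(
            f"pooled sample of {n_total} points cannot support k={k}")

    # exact PCA via the pooled covariance, accumulated in chunks so very
    # large (and float32) spectrum pools never get copied wholesale
    s1 = np.zeros(d)
    s2 = np.zeros((d, d))
    for a in arrays.values():
        for lo in range(0, a.shape[0], 65536):
            chunk = np.asarray(a[lo:lo + 65536], dtype=np.float64)
            s1 += chunk.sum(axis=0)
            s2 += chunk.T @ chunk
    mean = s1 / n_total
    cov = s2 / n_total - np.outer(mean, mean)
    evals, evecs = np.linalg.eigh(cov)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    evals = np.maximum(evals, 0.0)
    rank = int((evals > max(evals.max(), 1e-300) * 1e-10).sum())
    if k > rank:
        raise InsufficientDataError(
            f"k={k} exceeds the pooled sample rank {rank}")
    axes = evecs[:, :k].T.copy()
    for i in range(k):
        j = np.argmax(np.abs(axes[i]))
        if axes[i, j] < 0:
            axes[i] = -axes[i]

    def project(a: np.ndarray) -> np.ndarray:
        out = np.empty((a.shape[0], k))
        for lo in range(0, a.shape[0], 65536):
            chunk = np.asarray(a[lo:lo + 65536], dtype=np.float64)
            out[lo:lo + chunk.shape[0]] = (chunk - mean) @ axes.T
        return out

    out = {
        name: ReducedEnsemble(
            points=project(a), basis=axes, mean=mean,
            explained_variance=evals[:k].copy(),
            total_variance=float(evals.sum()), source=name)
        for name, a in arrays.items()
    }
    return out["sample"] if single else out


def twonn_intrinsic_dimension(points: np.ndarray,
                              discard_fraction: float = 0.10) -> float:
    """TwoNN intrinsic-dimension estimate.

    For every point take the ratio mu = r2 / r1 of its second to first
    nearest-neighbor distance; under a locally uniform density of dimension d,
    mu follows a Pareto law with CDF F(mu) = 1 - mu^(-d). The estimate is the
    slope of a through-origin fit of -log(1 - F_hat) against log(mu), after
    dropping the top ``discard_fraction`` of ratios (tail robustness).
    Duplicate points (zero first-neighbor distance) are dropped with a warning.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2:
        raise InsufficientDataError("points must be a 2D array")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=3)
    r1, r2 = d[:, 1], d[:, 2]
    ok = r1 > 0
    if not np.all(ok):
        warnings.warn(f"dropping {int((~ok).sum())} duplicate points "
                      "for the TwoNN estimate", stacklevel=2)
    if ok.sum() < 100:
        raise InsufficientDataError(
            "TwoNN needs at least 100 distinct points")
    mu = np.sort(r2[ok] / r1[ok])
    n = mu.size
    keep = int(np.floor(n * (1.0 - discard_fraction)))
    mu = mu[:keep]
    f_hat = np.arange(1, keep + 1) / (n + 1)
    x = np.log(mu)
    y = -np.log(1.0 - f_hat)
    pos = x > 0
    if pos.sum() < 10:
        raise InsufficientDataError("degenerate neighbor-ratio distribution")
    return float(np.dot(x[pos], y[pos]) / np.dot(x[pos], x[pos]))


def _unit_ball_volume(d: int) -> float:
    return float(np.exp(d / 2.0 * np.log(np.pi) - gammaln(d / 2.0 + 1.0)))


def knn_density_on_grid(points: np.ndarray, grid: GridSpec,
                        k_neighbors: int = 16,
                        extrapolation_neighbors: int = 3) -> GriddedDensity:
    """k-NN density estimate extrapolated to a regular grid.

    Point-wise densities rho(x_i) = k / (N * V_d * r_k(x_i)^d) are computed at
    the sample points, then each grid cell takes the inverse-distance-weighted
    average of the densities of its ``extrapolation_neighbors`` nearest sample
    points; the cell masses are normalized to 1.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise InsufficientDataError("need a non-empty (N, d) point set")
    if k_neighbors < 3:
        raise InsufficientDataError("k_neighbors must be >= 3")
    n, d = pts.shape
    if grid.ndim != d:
        raise IncompatibilityError(
            f"grid dimension {grid.ndim} does not match data dimension {d}")
    if k_neighbors >= n:
        raise InsufficientDataError("k_neighbors must be < number of points")

    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=k_neighbors + 1)
    rk = np.maximum(dist[:, -1], 1e-300)
    rho = k_neighbors / (n * _unit_ball_volume(d) * rk**d)

    cells = grid.cell_centers()
    cdist, cidx = tree.query(cells, k=extrapolation_neighbors)
    if extrapolation_neighbors == 1:
        cdist, cidx = cdist[:, None], cidx[:, None]
    wgt = 1.0 / np.maximum(cdist, 1e-12)
    dens = (rho[cidx] * wgt).sum(axis=1) / wgt.sum(axis=1)
    mass = dens / dens.sum()
    return GriddedDensity(grid=grid, mass=mass.reshape(grid.bins))


def jensen_shannon(p: GriddedDensity, q: GriddedDensity) -> float:
    """Jensen-Shannon divergence (natural log, in [0, ln 2]) between two
    densities on the same grid: JSD = KL(p||m)/2 + KL(q||m)/2, m = (p+q)/2."""
    if p.grid != q.grid:
        raise IncompatibilityError("densities live on different grids")
    a, b = p.mass.ravel(), q.mass.ravel()
    m = 0.5 * (a + b)

    def kl(x, mm):
        nz = x > 0
        return float(np.sum(x[nz] * np.log(x[nz] / mm[nz])))

    jsd = 0.5 * kl(a, m) + 0.5 * kl(b, m)
    return float(min(max(jsd, 0.0), np.log(2.0)))


def correlate_metrics(d_soap: Mapping[tuple, float] | Sequence[float],
                      jsd: Mapping[tuple, float] | Sequence[float]
                      ) -> tuple[float, float]:
    """Pearson r and Spearman rho between matched pair-distance lists.

    Mappings are matched by key; plain sequences must be equally long and
    already aligned.
    """
    if isinstance(d_soap, Mapping) and isinstance(jsd, Mapping):
        keys = sorted(d_soap)
        if sorted(jsd) != keys:
            raise IncompatibilityError("pair sets of the two metrics differ")
        x = np.array([d_soap[k] for k in keys], dtype=float)
        y = np.array([jsd[k] for k in keys], dtype=float)
    else:
        x = np.asarray(d_soap, dtype=float)
        y = np.asarray(jsd, dtype=float)
        if x.shape != y.shape:
            raise IncompatibilityError("metric lists have different lengths")
    if x.size < 3:
        raise InsufficientDataError("need at least 3 pairs to correlate")
    return float(pearsonr(x, y)[0]), float(spearmanr(x, y)[0])
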