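"""Gel/liquid phase detection from per-lipid spectra (PAMM-style).

Pipeline: pool the per-lipid power spectra of all temperatures of one force
field, reduce them to a handful of principal components in a single shared
basis, estimate the probability density of the reduced points with a Gaussian
KDE, climb the density with quick-shift mode seeking (each point links to its
nearest higher-density neighbor within a distance threshold; link roots are
the density modes), and fit one Gaussian per mode from the hard memberships.
The resulting mixture gives probabilistic phase assignments; the denser,
tighter-packed cluster is named GEL, the other(s) LIQUID.

Per-frame phase labels then yield interconversion (transition) matrices,
population-vs-temperature curves, and a bracketing interval for the melting
transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .divergence import ReducedEnsemble, pca_reduce
from .errors import IncompatibilityError, InsufficientDataError

__all__ = [
    "ClusterModel",
    "LabelTrajectory",
    "TransitionMatrix",
    "pool_and_reduce",
    "pamm_cluster",
    "assign_phase",
    "transition_matrix",
    "population_curve",
    "detect_transition",
    "GEL",
    "LIQUID",
]

GEL = "GEL"
LIQUID = "LIQUID"


@dataclass
class ClusterModel:
    """Density modes + Gaussian mixture fitted on the reduced space."""

    modes: np.ndarray                   # (c, k) density-peak locations
    weights: np.ndarray                 # (c,) mixture weights, sum to 1
    means: np.ndarray                   # (c, k)
    covariances: np.ndarray             # (c, k, k)
    labels_map: dict[int, str]          # cluster id -> GEL / LIQUID
    bandwidth: np.ndarray               # per-dimension KDE bandwidth used
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weights.size < 1:
            raise IncompatibilityError("a ClusterModel needs >= 1 cluster")
        if abs(float(self.weights.sum()) - 1.0) > 1e-9:
            raise IncompatibilityError("mixture weights must sum to 1")
        for c in self.covariances:
            if np.linalg.eigvalsh(c).min() <= 0:
                raise IncompatibilityError(
                    "covariances must be positive-definite")

    @property
    def n_clusters(self) -> int:
        return int(self.weights.size)

    def gel_cluster(self) -> int:
        for cid, name in self.labels_map.items():
            if name == GEL:
                return cid
        raise KeyError("model has no GEL cluster")


@dataclass
class LabelTrajectory:
    """Per-frame, per-lipid phase assignments at one temperature."""

    labels: np.ndarray                  # (n_frames, n_lipids) cluster ids
    temperature: float
    lag_ns: float = 10.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise IncompatibilityError("labels must be (n_frames, n_lipids)")


@dataclass
class TransitionMatrix:
    """Row-stochastic interconversion probabilities at a fixed lag."""

    matrix: np.ndarray
    counts: np.ndarray
    lag_ns: float
    undefined_rows: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.counts = np.asarray(self.counts)
        row_sums = self.matrix.sum(axis=1)
        defined = ~self.undefined_rows if self.undefined_rows.size else \
            np.ones(self.matrix.shape[0], bool)
        if not np.allclose(row_sums[defined], 1.0, atol=1e-9):
            raise IncompatibilityError("defined rows must sum to 1")


def pool_and_reduce(per_temperature_spectra: Mapping[float, np.ndarray],
                    k: int = 5) -> tuple[dict[float, ReducedEnsemble], np.ndarray]:
    """Fit one PCA on the pooled spectra of all temperatures and project each
    temperature into that shared basis, so different temperatures live in the
    same reduced parameter space and can be compared directly.

    Per-temperature spectra may be (N, D) or (n_frames, n_lipids, D); the
    frame structure is flattened for the fit but the returned scores keep the
    input's row order.
    """
    if len(per_temperature_spectra) < 2:
        raise InsufficientDataError("need spectra from >= 2 temperatures")
    flat: dict[float, np.ndarray] = {}
    lengths = set()
    for t, arr in per_temperature_spectra.items():
        a = np.asarray(arr, dtype=np.float64)
        a = a.reshape(-1, a.shape[-1])
        flat[t] = a
        lengths.add(a.shape[1])
    if len(lengths) != 1:
        raise IncompatibilityError(
            f"mismatched spectrum lengths across temperatures: {sorted(lengths)}")
    reduced = pca_reduce(flat, k)
    basis = next(iter(reduced.values())).basis
    return reduced, basis


def _silverman_bandwidth(points: np.ndarray, scale: float) -> np.ndarray:
    n, d = points.shape
    factor = (4.0 / ((d + 2.0) * n)) ** (1.0 / (d + 4.0))
    sd = points.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1e-12)
    return sd * factor * scale


def _kde_at_points(scaled: np.ndarray, chunk: int = 2048) -> np.ndarray:
    """Gaussian KDE density (up to a constant factor) at the sample points of
    a dataset already divided by its per-dimension bandwidths."""
    n = scaled.shape[0]
    out = np.empty(n)
    sq = (scaled**2).sum(axis=1)
    for a in range(0, n, chunk):
        b = min(a + chunk, n)
        d2 = sq[a:b, None] + sq[None, :] - 2.0 * scaled[a:b] @ scaled.T
        out[a:b] = np.exp(-0.5 * np.maximum(d2, 0.0)).sum(axis=1)
    return out / n


def pamm_cluster(points: np.ndarray, kde_bandwidth_scale: float = 1.0,
                 seed: int = 0, *, max_points: int = 12000,
                 quickshift_lambda: float = 3.0,
                 min_cluster_fraction: float = 0.005,
                 member_packing: np.ndarray | None = None) -> ClusterModel:
    """KDE + quick-shift + moment-fitted Gaussian mixture.

    ``member_packing`` optionally supplies a per-point packing observable
    (e.g. the lipid's Voronoi area): if given, the cluster with the lower
    mean packing value is named GEL; otherwise the cluster with the higher
    mean member density is (gel = tighter packing = denser mode).
    Deterministic for a given seed; at most ``max_points`` points enter the
    KDE/quick-shift stage (seeded subsample), the mixture then covers all
    points through its Gaussians.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 500:
        raise InsufficientDataError("PAMM clustering needs >= 500 points")
    if np.allclose(pts.std(axis=0), 0.0):
        raise InsufficientDataError("all points identical; nothing to cluster")

    rng = np.random.default_rng(seed)
    if pts.shape[0] > max_points:
        pick = np.sort(rng.choice(pts.shape[0], size=max_points, replace=False))
        sub = pts[pick]
        packing = None if member_packing is None else \
            np.asarray(member_packing)[pick]
    else:
        sub = pts
        packing = None if member_packing is None else np.asarray(member_packing)

    h = _silverman_bandwidth(sub, kde_bandwidth_scale)
    scaled = sub / h
    density = _kde_at_points(scaled)

    # quick-shift: link each point to its nearest strictly-higher-density
    # neighbor within tau = lambda * median nearest-neighbor distance
    tree = cKDTree(scaled)
    nn_d, _ = tree.query(scaled, k=2)
    # link threshold: lambda kernel bandwidths (= 1 in scaled units), or the
    # median nearest-neighbor spacing when the sample is sparser than that —
    # pure NN spacing strands low-density tail points as spurious modes
    tau = quickshift_lambda * max(1.0, float(np.median(nn_d[:, 1])))
    n = scaled.shape[0]
    parent = np.arange(n)
    order = np.argsort(density, kind="stable")   # stable rank breaks ties
    rank = np.empty(n, dtype=np.intp)
    rank[order] = np.arange(n)
    neigh_lists = tree.query_ball_point(scaled, tau)
    for i in range(n):
        idx = np.asarray(neigh_lists[i], dtype=np.intp)
        higher = idx[rank[idx] > rank[i]]
        if higher.size:
            d = np.linalg.norm(scaled[higher] - scaled[i], axis=1)
            parent[i] = higher[np.argmin(d)]

    # resolve links to roots
    root = parent.copy()
    for _ in range(n):
        nxt = root[root]
        if np.array_equal(nxt, root):
            break
        root = nxt
    modes_idx, assign = np.unique(root, return_inverse=True)

    # merge sub-threshold clusters into the nearest surviving mode
    min_size = max(1, int(np.ceil(min_cluster_fraction * n)))
    while True:
        sizes = np.bincount(assign, minlength=modes_idx.size)
        small = np.nonzero(sizes < min_size)[0]
        if small.size == 0 or modes_idx.size == 1:
            break
        keep = np.nonzero(sizes >= min_size)[0]
        if keep.size == 0:
            keep = np.array([np.argmax(sizes)])
        mode_pos = scaled[modes_idx]
        s = small[0]
        dists = np.linalg.norm(mode_pos[keep] - mode_pos[s], axis=1)
        target = keep[np.argmin(dists)]
        assign[assign == s] = target
        live = np.unique(assign)
        remap = {old: new for new, old in enumerate(live)}
        assign = np.array([remap[a] for a in assign])
        modes_idx = modes_idx[live]

    c = modes_idx.size
    k = sub.shape[1]
    weights = np.bincount(assign, minlength=c).astype(float)
    weights /= weights.sum()
    means = np.empty((c, k))
    covs = np.empty((c, k, k))
    mean_density = np.empty(c)
    for ci in range(c):
        mem = sub[assign == ci]
        means[ci] = mem.mean(axis=0)
        if mem.shape[0] > k:
            cov = np.cov(mem.T)
        else:
            cov = np.diag(h**2)
        cov = np.atleast_2d(cov)
        covs[ci] = cov + np.eye(k) * (1e-9 + 1e-6 * np.trace(cov) / k)
        mean_density[ci] = density[assign == ci].mean()

    if packing is not None:
        crit = np.array([packing[assign == ci].mean() for ci in range(c)])
        gel = int(np.argmin(crit))       # tighter packing -> smaller area
    else:
        gel = int(np.argmax(mean_density))
    labels_map = {ci: (GEL if ci == gel else LIQUID) for ci in range(c)}

    return ClusterModel(modes=sub[modes_idx], weights=weights, means=means,
                        covariances=covs, labels_map=labels_map,
                        bandwidth=h, seed=int(seed))


def _log_gauss(points: np.ndarray, mean: np.ndarray,
               cov: np.ndarray) -> np.ndarray:
    k = mean.size
    chol = np.linalg.cholesky(cov)
    diff = points - mean
    sol = np.linalg.solve(chol, diff.T)
    maha = (sol**2).sum(axis=0)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return -0.5 * (maha + logdet + k * np.log(2.0 * np.pi))


def assign_phase(points: np.ndarray,
                 model: ClusterModel) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-responsibility cluster per point, plus the responsibilities."""
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != model.means.shape[1]:
        raise IncompatibilityError(
            f"points of dimension {pts.shape[-1] if pts.ndim == 2 else '?'} "
            f"do not match the model's space ({model.means.shape[1]})")
    logp = np.stack([
        np.log(model.weights[c]) + _log_gauss(pts, model.means[c],
                                              model.covariances[c])
        for c in range(model.n_clusters)
    ], axis=1)
    logp -= logp.max(axis=1, keepdims=True)
    resp = np.exp(logp)
    resp /= resp.sum(axis=1, keepdims=True)
    return resp.argmax(axis=1), resp


def transition_matrix(traj: LabelTrajectory, *, lag_frames: int = 1,
                      n_clusters: int | None = None) -> TransitionMatrix:
    """Counts of (lipid, frame) -> (lipid, frame + lag) label pairs, with
    rows normalized to 1. Rows without any outgoing events are flagged."""
    lab = traj.labels
    if lab.shape[0] < 2 or lab.shape[0] <= lag_frames:
        raise InsufficientDataError(
            "kinetics need at least lag + 1 frames of labels")
    c = int(n_clusters if n_clusters is not None else lab.max() + 1)
    a = lab[:-lag_frames].ravel()
    b = lab[lag_frames:].ravel()
    counts = np.zeros((c, c), dtype=np.int64)
    np.add.at(counts, (a, b), 1)
    rows = counts.sum(axis=1)
    undefined = rows == 0
    matrix = np.zeros((c, c))
    nz = ~undefined
    matrix[nz] = counts[nz] / rows[nz, None]
    return TransitionMatrix(matrix=matrix, counts=counts,
                            lag_ns=traj.lag_ns * lag_frames,
                            undefined_rows=undefined)


def population_curve(trajectories: Mapping[float, LabelTrajectory] |
                     Sequence[LabelTrajectory],
                     model: ClusterModel) -> dict[float, dict[str, float]]:
    """Per-temperature fraction of (lipid, frame) observations per phase."""
    if isinstance(trajectories, Mapping):
        items = [(t, tr) for t, tr in trajectories.items()]
    else:
        items = [(tr.temperature, tr) for tr in trajectories]
    if not items:
        raise InsufficientDataError("need labels for at least one temperature")
    out: dict[float, dict[str, float]] = {}
    for t, tr in sorted(items):
        fracs: dict[str, float] = {GEL: 0.0, LIQUID: 0.0}
        total = tr.labels.size
        for cid, name in model.labels_map.items():
            fracs[name] = fracs.get(name, 0.0) + \
                float((tr.labels == cid).sum()) / total
        out[t] = fracs
    return out


def detect_transition(curve: Mapping[float, Mapping[str, float]] |
                      Mapping[float, float],
                      change_threshold: float = 0.5
                      ) -> tuple[float, float] | None:
    """Temperature interval bracketing the gel-fraction crossing of 0.5.

    Returns the (T_low, T_high) pair between which the gel fraction crosses
    one half, provided the total variation of the curve across the ladder
    exceeds ``change_threshold``; otherwise None (no sharp transition, as for
    force fields whose gel population grows on cooling but never dominates).
    """
    temps = sorted(curve)
    if len(temps) < 3:
        raise InsufficientDataError("need >= 3 temperatures to bracket")
    gel = []
    for t in temps:
        v = curve[t]
        gel.append(float(v[GEL]) if isinstance(v, Mapping) else float(v))
    gel_arr = np.asarray(gel)
    if gel_arr.max() - gel_arr.min() < change_threshold:
        return None
    for i in range(len(temps) - 1):
        lo, hi = gel_arr[i], gel_arr[i + 1]
        if (lo - 0.5) * (hi - 0.5) < 0 or (lo >= 0.5 > hi) or (lo > 0.5 >= hi):
            return (temps[i], temps[i + 1])
    return None
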