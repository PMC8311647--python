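"""Conventional ensemble-average membrane observables.

These are the low-dimensional baselines the SOAP metric is compared against:
area per lipid (APL), head-to-head bilayer thickness D_HH from the phosphate
density profile, the area compressibility modulus K_A from box-area
fluctuations, the lateral diffusion coefficient from the phosphate mean
square displacement, and per-lipid Voronoi areas (the tessellation control
for gel/liquid packing).

Units: lengths nm, times ns, K_A mN/m, diffusion cm^2/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import Voronoi

from .errors import InsufficientDataError, ParameterError
from .mapping import LOWER, UPPER, BeadFrame

__all__ = [
    "ObservableReport",
    "area_per_lipid",
    "density_profile",
    "bilayer_thickness",
    "area_compressibility",
    "lateral_diffusion",
    "voronoi_areas",
]

KB_J_PER_K = 1.380649e-23


@dataclass
class ObservableReport:
    """Bundle of the standard observables for one system."""

    apl_mean: float
    apl_sd: float
    d_hh: float | None
    profile_z: np.ndarray
    profile_density: np.ndarray
    k_a: float | None
    d_lat: float | None
    per_frame_apl: np.ndarray = field(default_factory=lambda: np.zeros(0))


def area_per_lipid(frames: Sequence[BeadFrame]) -> tuple[float, float]:
    """Mean and SD over frames of APL = Lx * Ly / (n_lipids / 2)."""
    frames = list(frames)
    if not frames:
        raise InsufficientDataError("need at least one frame")
    vals = []
    for fr in frames:
        n_up = int((fr.leaflet == UPPER).sum())
        n_lo = int((fr.leaflet == LOWER).sum())
        area = fr.box[0] * fr.box[1]
        if n_up != n_lo:
            warnings.warn(
                f"unequal leaflet occupancy ({n_up} vs {n_lo}); averaging "
                "the per-leaflet areas", stacklevel=2)
            vals.append(0.5 * (area / n_up + area / n_lo))
        else:
            vals.append(area / n_up)
    vals = np.asarray(vals)
    return float(vals.mean()), float(vals.std(ddof=0))


def density_profile(frames: Sequence[BeadFrame], site: int = 1,
                    bin_width: float = 0.1,
                    half_span: float | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged number density (nm^-3) of one bead site along z,
    midplane-centered per frame with symmetric bins.

    Returns (bin centers, density). The integral of the profile over z times
    the mean box area recovers the per-frame site count.
    """
    frames = list(frames)
    if not frames:
        raise InsufficientDataError("need at least one frame")
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    if half_span is None:
        half_span = max(
            float(np.abs(fr.coords[:, site, 2] - fr.coords[:, 1, 2].mean()).max())
            for fr in frames) + 3 * bin_width
    n_half = int(np.ceil(half_span / bin_width))
    edges = np.arange(-n_half, n_half + 1) * bin_width
    counts = np.zeros(edges.size - 1)
    area = 0.0
    for fr in frames:
        z = fr.coords[:, site, 2] - fr.coords[:, 1, 2].mean()
        counts += np.histogram(z, bins=edges)[0]
        area += fr.box[0] * fr.box[1]
    area /= len(frames)
    dens = counts / (len(frames) * area * bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, dens


def bilayer_thickness(profile_z: np.ndarray,
                      profile_density: np.ndarray) -> float:
    """Head-to-head thickness: distance between the density peaks of the two
    leaflets, with parabolic refinement around the maximal bins."""
    z = np.asarray(profile_z, dtype=float)
    rho = np.asarray(profile_density, dtype=float)
    neg, pos = z < 0, z > 0
    if rho[neg].max(initial=0) <= 0 or rho[pos].max(initial=0) <= 0:
        raise ParameterError(
            "profile lacks two resolvable leaflet peaks; thickness undefined")

    def refine(mask: np.ndarray) -> float:
        idx = np.nonzero(mask)[0]
        i = idx[np.argmax(rho[idx])]
        if 0 < i < z.size - 1 and rho[i - 1] > 0 and rho[i + 1] > 0:
            y0, y1, y2 = rho[i - 1], rho[i], rho[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                return float(z[i] + 0.5 * (y0 - y2) / denom * (z[1] - z[0]))
        return float(z[i])

    return refine(pos) - refine(neg)


def area_compressibility(area_series: np.ndarray,
                         temperature: float) -> float:
    """K_A = k_B T <A> / var(A) from total in-plane box-area fluctuations,
    in mN/m (areas in nm^2, temperature in K)."""
    a = np.asarray(area_series, dtype=float)
    if a.size < 100:
        raise InsufficientDataError(
            "compressibility needs >= 100 frames of fluctuating area")
    var = a.var(ddof=0)
    if var == 0:
        raise ParameterError("area series has zero variance (rigid box)")
    ka_n_per_m = KB_J_PER_K * temperature * a.mean() / var * 1e18
    return float(ka_n_per_m * 1e3)


def _unwrap_xy(phos: np.ndarray, boxes: np.ndarray) -> np.ndarray:
    """Remove periodic jumps from an (F, N, 2) phosphate xy trajectory."""
    out = phos.copy()
    for ax in range(2):
        d = np.diff(out[..., ax], axis=0)
        jumps = np.round(d / boxes[1:, None, ax]) * boxes[1:, None, ax]
        out[1:, :, ax] -= np.cumsum(jumps, axis=0)
    return out


def lateral_diffusion(frames: Sequence[BeadFrame],
                      fit_window: tuple[float, float] = (0.1, 0.5)
                      ) -> float:
    """Lateral diffusion coefficient of the phosphate sites, cm^2/s.

    xy MSD per leaflet with the leaflet center-of-mass motion removed
    (eliminates collective drift), linear fit over the lag window given as
    fractions of the trajectory length, D = slope / 4.
    """
    frames = list(frames)
    if len(frames) < 100:
        raise InsufficientDataError("diffusion needs >= 100 frames")
    times = np.array([fr.time for fr in frames])
    dt = np.diff(times)
    if not np.all(dt > 0):
        raise ParameterError("frame times must be strictly increasing")
    phos = np.stack([fr.phos[:, :2] for fr in frames])       # (F, N, 2)
    boxes = np.stack([fr.box[:2] for fr in frames])
    leaflet = frames[0].leaflet
    xy = _unwrap_xy(phos, boxes)
    for leaf in (UPPER, LOWER):
        sel = leaflet == leaf
        if sel.any():
            xy[:, sel, :] -= xy[:, sel, :].mean(axis=1, keepdims=True)

    F = xy.shape[0]
    lags = np.arange(max(1, int(fit_window[0] * F)),
                     max(2, int(fit_window[1] * F)))
    msd = np.empty(lags.size)
    for i, lag in enumerate(lags):
        d = xy[lag:] - xy[:-lag]
        msd[i] = (d**2).sum(axis=-1).mean()
    tau = lags * float(np.median(dt))
    slope = np.polyfit(tau, msd, 1)[0]            # nm^2 / ns
    return float(max(slope, 0.0) / 4.0 * 1e-5)    # -> cm^2/s


def _polygon_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def voronoi_areas(frame: BeadFrame) -> dict[int, np.ndarray]:
    """xy-periodic Voronoi tessellation of the phosphate sites, per leaflet.

    Returns {leaflet: per-lipid areas (nm^2) in lipid order within that
    leaflet}; areas of each leaflet sum to Lx * Ly.
    """
    out: dict[int, np.ndarray] = {}
    box = frame.box[:2]
    for leaf in (UPPER, LOWER):
        sel = np.nonzero(frame.leaflet == leaf)[0]
        if sel.size == 0:
            continue
        if sel.size < 3:
            raise InsufficientDataError(
                "Voronoi tessellation needs >= 3 lipids per leaflet")
        pts = frame.phos[sel, :2] % box
        shifts = np.array([(i, j) for i in (-1, 0, 1) for j in (-1, 0, 1)
                           if (i, j) != (0, 0)])
        tiled = np.concatenate(
            [pts] + [pts + s * box for s in shifts], axis=0)
        vor = Voronoi(tiled)
        areas = np.empty(sel.size)
        for i in range(sel.size):
            region = vor.regions[vor.point_region[i]]
            if -1 in region or len(region) == 0:
                raise ParameterError(
                    "degenerate configuration: unbounded Voronoi cell")
            areas[i] = _polygon_area(vor.vertices[region])
        out[leaf] = areas
    return out
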