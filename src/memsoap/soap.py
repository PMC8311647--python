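"""SOAP power spectra for phosphate-centered lipid environments.

The Smooth Overlap of Atomic Positions descriptor encodes the neighborhood of
a center as follows: the positions of all sites of each species ``alpha``
within a cutoff are smoothed into a Gaussian density field

    rho_alpha(r) = sum_j exp(-|r - r_j|^2 / (2 sigma^2)),

the field is expanded onto orthonormal radial functions ``g_n`` and real
spherical harmonics ``Y_lm``,

    c^alpha_nlm = integral g_n(r) Y_lm(r^) rho_alpha(r) d^3r,

and the expansion coefficients are contracted over ``m`` into the
rotation-invariant power spectrum

    p^{alpha beta}_{n n' l} = pi * sqrt(8 / (2l + 1)) * sum_m
                              c^alpha_nlm c^beta_n'lm.

The expansion integral is evaluated analytically via the plane-wave-free
Gaussian identity  exp(-a|r - R|^2) = exp(-a(r^2 + R^2)) * sum_lm 4 pi
i_l(2 a r R) Y_lm(r^) Y_lm(R^),  which reduces each coefficient to a smooth
one-dimensional radial integral per (n, l, neighbor distance). Those radial
integrals are precomputed on a dense grid and cubic-spline interpolated, so a
whole frame is processed in a few vectorized passes.

Radial basis: the polynomial set phi_k(r) = (r_cut - r)^(k+2), k = 1..n_max,
Löwdin-orthonormalized under the measure r^2 dr on [0, r_cut]. It has exact
finite support, so the radial integration window is [0, r_cut] and the
closed-form overlap matrix keeps the orthonormalization stable up to
n_max = 8 in float64.

The bilayer is a slab: periodicity applies in x and y only, implemented by
explicit in-plane image replication within the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy.interpolate import CubicSpline
from scipy.linalg import eigh
from scipy.spatial import cKDTree
from scipy.special import ive
from numpy.polynomial.legendre import leggauss

from .errors import DegenerateEnvironmentError, ParameterError
from .mapping import SITE_LABELS, BeadFrame
from .sph import real_sph_harm

__all__ = [
    "SoapParams",
    "PowerSpectrum",
    "compute_power_spectrum",
    "compute_frame_spectra",
    "frame_spectra_array",
    "normalize_spectrum",
    "spectrum_length",
]

SINGLE_LIPID = "SINGLE_LIPID"
FRAME_AVERAGE = "FRAME_AVERAGE"
ENSEMBLE_AVERAGE = "ENSEMBLE_AVERAGE"


@dataclass(frozen=True)
class SoapParams:
    """Parameterization of the descriptor.

    Defaults follow the bilayer setting this package targets: n_max = 8,
    l_max = 8, sigma = 0.1 nm density smoothing, 3 nm cutoff (large enough to
    reach the tail sites at mid-membrane, small enough to exclude the opposite
    leaflet's head groups), xy periodicity.
    """

    n_max: int = 8
    l_max: int = 8
    sigma: float = 0.1
    r_cut: float = 3.0
    species: tuple[str, ...] = SITE_LABELS
    periodic_xy: bool = True
    radial_basis: str = "polynomial"

    def __post_init__(self) -> None:
        if self.n_max < 1:
            raise ParameterError("n_max must be >= 1")
        if self.l_max < 0:
            raise ParameterError("l_max must be >= 0")
        if self.sigma <= 0:
            raise ParameterError("sigma must be positive")
        if self.r_cut <= 0:
            raise ParameterError("r_cut must be positive")
        if len(self.species) != 4 or len(set(self.species)) != 4:
            raise ParameterError("species must be 4 unique site labels")
        if self.radial_basis != "polynomial":
            raise ParameterError("only the polynomial radial basis is implemented")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def vector_length(self) -> int:
        return spectrum_length(self.n_max, self.l_max, self.n_species)


def spectrum_length(n_max: int, l_max: int, n_species: int = 4) -> int:
    """Number of unique power-spectrum components: same-species blocks keep
    n <= n', cross-species blocks keep all (n, n'), each times (l_max + 1)."""
    same = n_species * (n_max * (n_max + 1) // 2)
    cross = (n_species * (n_species - 1) // 2) * n_max * n_max
    return (l_max + 1) * (same + cross)


@dataclass
class PowerSpectrum:
    """A SOAP power spectrum vector with its provenance."""

    vector: np.ndarray
    params: SoapParams
    center_kind: str = SINGLE_LIPID
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=np.float64).reshape(-1)
        if self.vector.size != self.params.vector_length:
            raise ParameterError(
                f"vector length {self.vector.size} does not match params "
                f"({self.params.vector_length})")
        if not np.all(np.isfinite(self.vector)):
            raise DegenerateEnvironmentError("non-finite power spectrum")


# --------------------------------------------------------------------------
# engine: per-params precomputed tables
# --------------------------------------------------------------------------

_ENGINES: dict[tuple, "_SoapEngine"] = {}


def _get_engine(params: SoapParams) -> "_SoapEngine":
    key = (params.n_max, params.l_max, params.sigma, params.r_cut,
           params.n_species)
    eng = _ENGINES.get(key)
    if eng is None:
        eng = _SoapEngine(params)
        _ENGINES[key] = eng
    return eng


def _scaled_sph_bessel_i(l_values: np.ndarray, z: np.ndarray) -> np.ndarray:
    """i_l(z) * exp(-z) for z >= 0, via the scaled Bessel function ive."""
    zc = np.maximum(z, 1e-14)
    return np.sqrt(np.pi / (2.0 * zc)) * ive(l_values + 0.5, zc)


class _SoapEngine:
    """Orthonormalized radial basis + splined radial integrals for one
    (n_max, l_max, sigma, r_cut) combination."""

    #: quadrature nodes per radial window
    N_QUAD = 64
    #: radial-integral spline resolution
    N_GRID = 4096
    #: Gaussian support half-width in units of sigma
    W_SIGMA = 8.0

    def __init__(self, params: SoapParams) -> None:
        self.params = params
        n, lmax, rc = params.n_max, params.l_max, params.r_cut
        self.alpha = 1.0 / (2.0 * params.sigma**2)

        # Löwdin orthonormalization of phi_k(r) = (rc - r)^(k+2)
        k = np.arange(1, n + 1)
        e = k[:, None] + k[None, :] + 4            # exponent of (rc - r)
        S = 2.0 * rc ** (e + 3) / ((e + 1) * (e + 2) * (e + 3))
        w_eig, v_eig = eigh(S)
        w_eig = np.maximum(w_eig, w_eig.max() * 1e-15)
        self.W = v_eig @ np.diag(1.0 / np.sqrt(w_eig)) @ v_eig.T

        self._nodes, self._weights = leggauss(self.N_QUAD)
        grid = np.linspace(0.0, rc, self.N_GRID + 1)
        table = self._radial_integrals(grid)        # (grid, n, lmax+1)
        self._spline = CubicSpline(grid, table.reshape(grid.size, -1), axis=0)
        self._build_flatten_index()

    # -- radial machinery ---------------------------------------------------

    def _basis(self, r: np.ndarray) -> np.ndarray:
        """g_n(r) for r in [0, rc]; shape (..., n_max)."""
        rc = self.params.r_cut
        k = np.arange(1, self.params.n_max + 1)
        phi = np.clip(rc - r[..., None], 0.0, None) ** (k + 2)
        return phi @ self.W.T

    def _radial_integrals(self, R: np.ndarray) -> np.ndarray:
        """I_nl(R) = int r^2 g_n(r) exp(-a (r-R)^2) i~_l(2 a r R) dr over the
        Gaussian window intersected with [0, r_cut]; shape (len(R), n, l+1)."""
        p = self.params
        a = self.alpha
        half = self.W_SIGMA * p.sigma
        lo = np.clip(R - half, 0.0, p.r_cut)
        hi = np.clip(R + half, 0.0, p.r_cut)
        mid, rad = 0.5 * (hi + lo), 0.5 * (hi - lo)
        r = mid[:, None] + rad[:, None] * self._nodes[None, :]   # (R, q)
        w = rad[:, None] * self._weights[None, :]
        ls = np.arange(p.l_max + 1)
        # exp(-a(r-R)^2) * scaled bessel, batched over l
        gauss = np.exp(-a * (r - R[:, None]) ** 2)
        z = 2.0 * a * r * R[:, None]
        bess = _scaled_sph_bessel_i(ls[:, None, None], z[None])  # (l, R, q)
        g = self._basis(r)                                        # (R, q, n)
        integrand = (r * r * gauss)[None] * bess                  # (l, R, q)
        out = np.einsum("lrq,rq,rqn->rnl", integrand, w, g, optimize=True)
        return out

    def radial(self, R: np.ndarray, exact: bool = False) -> np.ndarray:
        """I_nl at arbitrary distances, splined (default) or re-integrated."""
        if exact:
            return self._radial_integrals(R)
        p = self.params
        flat = self._spline(np.clip(R, 0.0, p.r_cut))
        return flat.reshape(R.size, p.n_max, p.l_max + 1)

    # -- power-spectrum flattening ------------------------------------------

    def _build_flatten_index(self) -> None:
        p = self.params
        S, n, L = p.n_species, p.n_max, p.l_max + 1
        s_i, t_i, n_i, k_i, l_i, w_i = [], [], [], [], [], []
        for s in range(S):
            for t in range(s, S):
                for l in range(L):
                    for a in range(n):
                        for b in range(a if s == t else 0, n):
                            s_i.append(s)
                            t_i.append(t)
                            n_i.append(a)
                            k_i.append(b)
                            l_i.append(l)
                            w_i.append(1.0 if (s == t and a == b) else np.sqrt(2.0))
        self._flat = tuple(np.asarray(x) for x in (s_i, t_i, n_i, k_i, l_i))
        self._flat_w = np.asarray(w_i)
        assert self._flat_w.size == p.vector_length

    def flatten(self, p_full: np.ndarray) -> np.ndarray:
        """(C, S, S, n, n, L) full tensor -> (C, vector_length) with the
        sqrt(2) weighting that preserves dot products."""
        s_i, t_i, n_i, k_i, l_i = self._flat
        return p_full[:, s_i, t_i, n_i, k_i, l_i] * self._flat_w[None, :]


# --------------------------------------------------------------------------
# frame-level computation
# --------------------------------------------------------------------------

def _neighbor_pairs(frame: BeadFrame, params: SoapParams,
                    centers: np.ndarray):
    """All (center, site) pairs within r_cut, across xy periodic images.

    Returns (center_index, species_index, displacement) arrays.
    """
    rc = params.r_cut
    box = frame.box
    centers = centers.copy()
    sites = frame.coords.reshape(-1, 3).copy()               # (n*4, 3)
    if params.periodic_xy:
        if rc >= min(box[0], box[1]) / 2.0:
            raise ParameterError(
                f"r_cut = {rc} must be < half the smallest periodic box edge "
                f"(box = {box[0]:.3f} x {box[1]:.3f} nm): periodic images are "
                "ambiguous otherwise")
        # wrap into the primary box so the +-1 image tiling always covers
        # every center's cutoff sphere
        for ax in (0, 1):
            sites[:, ax] %= box[ax]
            centers[:, ax] %= box[ax]
        shifts = np.array([(i, j, 0.0) for i in (-1, 0, 1) for j in (-1, 0, 1)])
        shifts = shifts * np.array([box[0], box[1], 1.0])
    else:
        shifts = np.zeros((1, 3))
    species = np.tile(np.arange(4), frame.n_lipids)
    tiled = (sites[None, :, :] + shifts[:, None, :]).reshape(-1, 3)
    tiled_species = np.tile(species, shifts.shape[0])

    tree = cKDTree(tiled)
    neigh = tree.query_ball_point(centers, rc)
    counts = np.fromiter((len(x) for x in neigh), dtype=np.intp,
                         count=len(neigh))
    flat = np.concatenate([np.asarray(x, dtype=np.intp) for x in neigh]) \
        if counts.sum() else np.empty(0, dtype=np.intp)
    center_idx = np.repeat(np.arange(centers.shape[0]), counts)
    disp = tiled[flat] - centers[center_idx]
    return center_idx, tiled_species[flat], disp


def frame_spectra_array(frame: BeadFrame, params: SoapParams,
                        *, centers: np.ndarray | None = None,
                        exact_radial: bool = False,
                        chunk_pairs: int = 200_000) -> np.ndarray:
    """Power spectra for every lipid of a frame as an (n_centers, D) array.

    Centers default to all phosphate sites. This is the fast batched path;
    :func:`compute_frame_spectra` wraps it in PowerSpectrum objects.
    """
    eng = _get_engine(params)
    if centers is None:
        centers = frame.phos
    centers = np.asarray(centers, dtype=np.float64).reshape(-1, 3)
    C = centers.shape[0]
    S, n_max, L = params.n_species, params.n_max, params.l_max + 1
    n_lm = L * L
    l_of_lm = np.concatenate([np.full(2 * l + 1, l) for l in range(L)])

    cidx, sidx, disp = _neighbor_pairs(frame, params, centers)
    c = np.zeros((C * S, n_max, n_lm))
    if cidx.size:
        group = cidx * S + sidx
        order = np.argsort(group, kind="stable")
        group, disp = group[order], disp[order]
        R = np.linalg.norm(disp, axis=1)
        for a in range(0, group.size, chunk_pairs):
            b = min(a + chunk_pairs, group.size)
            Y = real_sph_harm(params.l_max, disp[a:b])            # (P, n_lm)
            I = eng.radial(R[a:b], exact=exact_radial)            # (P, n, L)
            contrib = (4.0 * np.pi) * I[:, :, l_of_lm] * Y[:, None, :]
            g = group[a:b]
            starts = np.nonzero(np.r_[True, g[1:] != g[:-1]])[0]
            sums = np.add.reduceat(contrib, starts, axis=0)
            np.add.at(c, g[starts], sums)
    c = c.reshape(C, S, n_max, n_lm)

    # contract over m: p[c, s, t, n, k, l]
    p_full = np.empty((C, S, S, n_max, n_max, L))
    pref = np.pi * np.sqrt(8.0 / (2.0 * np.arange(L) + 1.0))
    for l in range(L):
        sl = slice(l * l, (l + 1) * (l + 1))
        p_full[..., l] = pref[l] * np.einsum(
            "csnm,ctkm->cstnk", c[..., sl], c[..., sl], optimize=True)
    return eng.flatten(p_full)


def compute_frame_spectra(frame: BeadFrame, params: SoapParams,
                          **kwargs) -> list[PowerSpectrum]:
    """One SINGLE_LIPID spectrum per lipid, centered on each phosphate."""
    arr = frame_spectra_array(frame, params, **kwargs)
    return [
        PowerSpectrum(vector=arr[i], params=params, center_kind=SINGLE_LIPID,
                      provenance={"center": i, "time": frame.time})
        for i in range(arr.shape[0])
    ]


def compute_power_spectrum(frame: BeadFrame, center: int,
                           params: SoapParams, **kwargs) -> PowerSpectrum:
    """Spectrum of the environment of one lipid (by index)."""
    if not (0 <= center < frame.n_lipids):
        raise ParameterError(
            f"center index {center} out of range for {frame.n_lipids} lipids")
    arr = frame_spectra_array(frame, params,
                              centers=frame.phos[center:center + 1], **kwargs)
    return PowerSpectrum(vector=arr[0], params=params,
                         center_kind=SINGLE_LIPID,
                         provenance={"center": center, "time": frame.time})


def normalize_spectrum(p: PowerSpectrum) -> PowerSpectrum:
    """Return the unit-Euclidean-norm copy of a spectrum."""
    norm = float(np.linalg.norm(p.vector))
    if norm == 0.0:
        raise DegenerateEnvironmentError("cannot normalize a zero spectrum")
    return PowerSpectrum(vector=p.vector / norm, params=p.params,
                         center_kind=p.center_kind,
                         provenance=dict(p.provenance))
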