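"""Synthetic two-leaflet bilayer configurations with known ground truth.

No physics is simulated: frames are built geometrically so that every planted
property (phase labels, packing, kinetics, observables) is known exactly.

* Each leaflet is a periodic triangular lattice of phosphate sites; the
  lattice constant realizes the frame's area per lipid. Gel lipids carry
  small positional jitter and straight, narrowly splayed tails (hexagonal
  order); liquid lipids get large jitter and widely splayed tails (disorder).
* Contiguous gel domains are laterally contracted toward their centroid by
  sqrt(apl_gel / apl_frame), so gel lipids are tighter packed (smaller
  Voronoi areas), as in a real gel domain.
* Phase labels evolve as per-lipid two-state Markov chains, optionally
  neighbor-coupled on the lattice (flip rates boosted by the gel fraction of
  the six lattice neighbors), which produces nucleating, spatially contiguous
  domains instead of salt-and-pepper mixtures.
* Default geometry: phosphate planes at z = +-1.9 nm, head groups at
  +-2.3 nm, tail sites at +-0.5 nm (head-to-head thickness 3.8 nm, in the
  range spanned by common lipid models); default areas per lipid 0.47 nm^2
  (gel) and 0.64 nm^2 (liquid), typical of PC lipids below/above melting.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .mapping import LOWER, UPPER, BeadFrame

__all__ = [
    "SyntheticSpec",
    "generate_bilayer",
    "generate_trajectory",
    "generate_temperature_ladder",
    "generate_ff_ensemble_ladder",
    "lattice_shape",
    "lattice_neighbors",
    "SHARP",
    "GRADUAL",
]

SHARP = "SHARP"
GRADUAL = "GRADUAL"

Z_PHOS = 1.9
Z_HEAD = 2.3
Z_TAIL = 0.5
TAIL_BASE_SPLAY = 0.15       # fixed half-distance between the two tails, nm
AR1_RHO = 0.5                # frame-to-frame jitter correlation


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters; defaults are the package's stated test world."""

    n_lipids: int = 128
    apl_gel: float = 0.47
    apl_liquid: float = 0.64
    noise_gel: float = 0.03
    noise_liquid: float = 0.12
    tail_spread_gel: float = 0.05
    tail_spread_liquid: float = 0.30
    domain: tuple[float, float, float] | None = None   # (cx, cy, radius) nm
    p_gel_to_liquid: float = 0.0
    p_liquid_to_gel: float = 0.0
    neighbor_coupling: float = 0.0
    nucleation_only: bool = False      # liquid->gel only next to existing gel
    initial_phase: str | None = None   # None / "GEL" / "LIQUID"
    n_frames: int = 1
    temperature: float = 303.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lipids < 2 or self.n_lipids % 2:
            raise ConfigurationError("n_lipids must be even and >= 2")
        for p in (self.p_gel_to_liquid, self.p_liquid_to_gel):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("kinetic probabilities must be in [0, 1]")
        if self.apl_gel <= 0 or self.apl_liquid <= 0:
            raise ConfigurationError("areas per lipid must be positive")
        if self.initial_phase not in (None, "GEL", "LIQUID"):
            raise ConfigurationError("initial_phase must be GEL, LIQUID or None")


def lattice_shape(n_per_leaflet: int) -> tuple[int, int]:
    """(nx, ny) with nx * ny = n, ny even, as close to square as possible."""
    best = None
    for ny in range(2, n_per_leaflet + 1, 2):
        if n_per_leaflet % ny:
            continue
        nx = n_per_leaflet // ny
        score = abs(np.log(nx / ny))
        if best is None or score < best[0]:
            best = (score, nx, ny)
    if best is None:
        raise ConfigurationError(
            f"cannot factor {n_per_leaflet} lipids per leaflet into an even-row "
            "lattice")
    return best[1], best[2]


def lattice_neighbors(nx: int, ny: int) -> np.ndarray:
    """(n, 6) indices of the six triangular-lattice neighbors with periodic
    wrap; row-major site order (i + nx * j)."""
    idx = np.arange(nx * ny)
    i, j = idx % nx, idx // nx
    odd = (j % 2).astype(bool)
    di_side = np.where(odd, 1, -1)
    neigh = np.stack([
        (i + 1) % nx + nx * j,
        (i - 1) % nx + nx * j,
        i + nx * ((j + 1) % ny),
        i + nx * ((j - 1) % ny),
        (i + di_side) % nx + nx * ((j + 1) % ny),
        (i + di_side) % nx + nx * ((j - 1) % ny),
    ], axis=1)
    return neigh


def _lattice_xy(nx: int, ny: int, a: float,
                shift: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    h = a * np.sqrt(3.0) / 2.0
    idx = np.arange(nx * ny)
    i, j = idx % nx, idx // nx
    x = (i + 0.5 * (j % 2)) * a + shift[0]
    y = j * h + shift[1]
    return np.stack([x, y], axis=1)


def _gel_components(gel_mask: np.ndarray, neigh: np.ndarray) -> list[np.ndarray]:
    """Connected components of the gel sites on the lattice graph."""
    seen = np.zeros(gel_mask.size, dtype=bool)
    comps = []
    for start in np.nonzero(gel_mask)[0]:
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in neigh[u]:
                if gel_mask[v] and not seen[v]:
                    seen[v] = True
                    stack.append(v)
        comps.append(np.asarray(comp))
    return comps


def _unwrapped_component(xy: np.ndarray, comp: np.ndarray, neigh: np.ndarray,
                         box: np.ndarray) -> np.ndarray:
    """Coordinates of one connected component unwrapped by BFS minimum image
    so its centroid is well defined."""
    pos = {int(comp[0]): xy[comp[0]].copy()}
    order = [int(comp[0])]
    inset = set(int(x) for x in comp)
    qi = 0
    while qi < len(order):
        u = order[qi]
        qi += 1
        for v in neigh[u]:
            v = int(v)
            if v in inset and v not in pos:
                d = xy[v] - xy[u]
                d -= np.round(d / box) * box
                pos[v] = pos[u] + d
                order.append(v)
    return np.stack([pos[int(c)] for c in comp])


class _JitterState:
    """Per-lipid AR(1) standardized noise, advanced frame by frame."""

    def __init__(self, rng: np.random.Generator, shape: tuple[int, ...]):
        self.rng = rng
        self.state = rng.standard_normal(shape)

    def advance(self) -> np.ndarray:
        eps = self.rng.standard_normal(self.state.shape)
        self.state = AR1_RHO * self.state + np.sqrt(1 - AR1_RHO**2) * eps
        return self.state


def _initial_labels(spec: SyntheticSpec, rng: np.random.Generator,
                    xy_upper: np.ndarray, xy_lower: np.ndarray,
                    box: np.ndarray) -> np.ndarray:
    n = spec.n_lipids
    if spec.initial_phase == "GEL":
        labels = np.ones(n, dtype=np.int8)
    elif spec.initial_phase == "LIQUID":
        labels = np.zeros(n, dtype=np.int8)
    else:
        pg, pl = spec.p_gel_to_liquid, spec.p_liquid_to_gel
        if pg + pl > 0:
            f = pl / (pg + pl)
            labels = (rng.random(n) < f).astype(np.int8)
        else:
            labels = np.zeros(n, dtype=np.int8)
    if spec.domain is not None:
        cx, cy, r = spec.domain
        if 2 * r > min(box[0], box[1]):
            raise ConfigurationError(
                f"domain of radius {r} nm does not fit the "
                f"{box[0]:.2f} x {box[1]:.2f} nm box")
        for xy, sl in ((xy_upper, slice(0, n // 2)),
                       (xy_lower, slice(n // 2, n))):
            d = xy - np.array([cx, cy])
            d -= np.round(d / box[:2]) * box[:2]
            inside = (d**2).sum(axis=1) < r * r
            labels[sl][inside] = 1
    return labels


def _advance_labels(labels: np.ndarray, spec: SyntheticSpec,
                    neigh: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One Markov step; per-leaflet lattices are independent graphs."""
    n = labels.size
    npl = n // 2
    out = labels.copy()
    for sl in (slice(0, npl), slice(npl, n)):
        lab = labels[sl]
        p_gl = np.full(npl, spec.p_gel_to_liquid)
        p_lg = np.full(npl, spec.p_liquid_to_gel)
        if spec.nucleation_only:
            f_gel = lab[neigh].mean(axis=1)
            p_lg = np.where(f_gel > 0, p_lg, 0.0)   # growth by adjacency only
        elif spec.neighbor_coupling > 0:
            f_gel = lab[neigh].mean(axis=1)
            c = spec.neighbor_coupling
            p_lg = np.clip(p_lg * (1 + c * f_gel), 0, 1)
            p_gl = np.clip(p_gl * (1 + c * (1 - f_gel)), 0, 1)
        u = rng.random(npl)
        flip = np.where(lab == 1, u < p_gl, u < p_lg)
        out[sl] = np.where(flip, 1 - lab, lab)
    return out


def _build_frame(spec: SyntheticSpec, labels: np.ndarray,
                 nx: int, ny: int, neigh: np.ndarray,
                 jitter: np.ndarray, angles: np.ndarray,
                 time: float) -> BeadFrame:
    """Assemble a BeadFrame from the current labels and jitter state."""
    n = spec.n_lipids
    npl = n // 2
    f_gel = float(labels.mean())
    apl_frame = f_gel * spec.apl_gel + (1 - f_gel) * spec.apl_liquid
    a = np.sqrt(2.0 * apl_frame / np.sqrt(3.0))
    box = np.array([nx * a, ny * a * np.sqrt(3.0) / 2.0, 2 * Z_HEAD + 2.0])

    gamma = np.sqrt(spec.apl_gel / apl_frame)
    noise = np.where(labels == 1, spec.noise_gel, spec.noise_liquid)
    spread = np.where(labels == 1, spec.tail_spread_gel,
                      spec.tail_spread_liquid)

    coords = np.empty((n, 4, 3))
    for leaf, (sl, sgn, shift) in enumerate((
            (slice(0, npl), +1.0, (0.0, 0.0)),
            (slice(npl, n), -1.0, (a / 2.0, a * np.sqrt(3.0) / 4.0)))):
        xy = _lattice_xy(nx, ny, a, shift)
        lab = labels[sl]
        if 0.0 < f_gel < 1.0:
            for comp in _gel_components(lab == 1, neigh):
                if comp.size < 2:
                    continue
                unwrapped = _unwrapped_component(xy, comp, neigh, box[:2])
                centroid = unwrapped.mean(axis=0)
                xy[comp] = centroid + gamma * (unwrapped - centroid)
        jit = jitter[sl]                       # (npl, 8) standardized AR(1)
        nz = noise[sl][:, None]
        phos_xy = xy + nz * jit[:, 0:2]
        phos_z = sgn * Z_PHOS + 0.5 * nz[:, 0] * jit[:, 2]
        head_xy = phos_xy + 0.5 * nz * jit[:, 3:5]
        head_z = sgn * Z_HEAD + 0.5 * nz[:, 0] * jit[:, 5]
        u = np.stack([np.cos(angles[sl]), np.sin(angles[sl])], axis=1)
        sp = spread[sl][:, None]
        t1_xy = phos_xy + TAIL_BASE_SPLAY * u + sp * jit[:, 6:8]
        t2_xy = phos_xy - TAIL_BASE_SPLAY * u - sp * jit[:, 6:8][:, ::-1]
        tail_z = sgn * Z_TAIL
        coords[sl, 1, 0:2] = phos_xy
        coords[sl, 1, 2] = phos_z
        coords[sl, 0, 0:2] = head_xy
        coords[sl, 0, 2] = head_z
        coords[sl, 2, 0:2] = t1_xy
        coords[sl, 2, 2] = tail_z
        coords[sl, 3, 0:2] = t2_xy
        coords[sl, 3, 2] = tail_z
    coords[..., 0] %= box[0]
    coords[..., 1] %= box[1]
    leaflet = np.concatenate([np.full(npl, UPPER, np.int8),
                              np.full(npl, LOWER, np.int8)])
    return BeadFrame(coords=coords, box=box, time=time, leaflet=leaflet)


def generate_bilayer(spec: SyntheticSpec) -> tuple[BeadFrame, np.ndarray]:
    """One frame plus its ground-truth labels (1 = gel, 0 = liquid)."""
    frames, labels = generate_trajectory(replace(spec, n_frames=1))
    return frames[0], labels[0]


def generate_trajectory(spec: SyntheticSpec
                        ) -> tuple[list[BeadFrame], np.ndarray]:
    """A sequence of frames with evolving labels.

    Returns (frames, labels) with labels of shape (n_frames, n_lipids);
    frame times advance in 10 ns steps (the analysis sampling interval).
    """
    rng = np.random.default_rng(spec.seed)
    npl = spec.n_lipids // 2
    nx, ny = lattice_shape(npl)
    neigh = lattice_neighbors(nx, ny)

    # probe box (liquid APL) only to validate / place the domain
    a0 = np.sqrt(2.0 * spec.apl_liquid / np.sqrt(3.0))
    box0 = np.array([nx * a0, ny * a0 * np.sqrt(3.0) / 2.0, 2 * Z_HEAD + 2.0])
    lab = _initial_labels(spec, rng, _lattice_xy(nx, ny, a0),
                          _lattice_xy(nx, ny, a0, (a0 / 2, a0 * 0.433)),
                          box0)

    angles = rng.uniform(0, 2 * np.pi, spec.n_lipids)
    jitter = _JitterState(rng, (spec.n_lipids, 8))

    frames: list[BeadFrame] = []
    labels = np.empty((spec.n_frames, spec.n_lipids), dtype=np.int8)
    for f in range(spec.n_frames):
        if f > 0:
            lab = _advance_labels(lab, spec, neigh, rng)
            jitter.advance()
        labels[f] = lab
        frames.append(_build_frame(spec, lab, nx, ny, neigh,
                                   jitter.state, angles, time=10.0 * f))
    return frames, labels


def _sharp_fraction(t: float, t_mid: float = 310.0, width: float = 6.0) -> float:
    return float(1.0 / (1.0 + np.exp((t - t_mid) / width)))


def _gradual_fraction(t: float) -> float:
    return float(np.clip(0.45 - 0.002 * (t - 273.0), 0.0, 1.0))


def generate_temperature_ladder(
        base_spec: SyntheticSpec, temps: Sequence[float], mode: str = SHARP,
        *, rate_scale: float = 0.16,
) -> dict[float, tuple[list[BeadFrame], np.ndarray]]:
    """Trajectories across a temperature ladder.

    SHARP emulates a wet-CG-like melting transition: the equilibrium gel
    fraction follows a steep sigmoid crossing 0.5 inside the ladder (midpoint
    310 K, width 6 K). GRADUAL emulates the dry-CG behavior: gel content
    drifts shallowly with temperature and never becomes dominant. Kinetic
    rates are chosen per temperature so the chain's stationary gel fraction
    matches the target curve, including the mean-field correction for the
    neighbor coupling.
    """
    if len(temps) < 3:
        raise ConfigurationError("a temperature ladder needs >= 3 temperatures")
    if mode not in (SHARP, GRADUAL):
        raise ConfigurationError(f"unknown ladder mode {mode!r}")
    seeds = np.random.SeedSequence(base_spec.seed).spawn(len(temps))
    out: dict[float, tuple[list[BeadFrame], np.ndarray]] = {}
    c = base_spec.neighbor_coupling
    for t, ss in zip(temps, seeds):
        f = _sharp_fraction(t) if mode == SHARP else _gradual_fraction(t)
        f = min(max(f, 1e-4), 1 - 1e-4)
        # stationary fraction of the coupled chain at homogeneous f:
        # p_lg (1 + c f) / (p_gl (1 + c (1 - f))) = f / (1 - f)
        p_lg = rate_scale * f / (1 + c * f)
        p_gl = rate_scale * (1 - f) / (1 + c * (1 - f))
        spec_t = replace(
            base_spec, temperature=float(t),
            p_gel_to_liquid=min(p_gl, 1.0), p_liquid_to_gel=min(p_lg, 1.0),
            initial_phase=None, domain=None,
            seed=int(ss.generate_state(1)[0] % (2**31 - 1)))
        # equilibrium start: draw initial labels at the target fraction
        frames, labels = _generate_with_initial_fraction(spec_t, f)
        out[float(t)] = (frames, labels)
    return out


def _generate_with_initial_fraction(spec: SyntheticSpec, f: float
                                    ) -> tuple[list[BeadFrame], np.ndarray]:
    rng = np.random.default_rng(spec.seed)
    npl = spec.n_lipids // 2
    nx, ny = lattice_shape(npl)
    neigh = lattice_neighbors(nx, ny)
    lab = (rng.random(spec.n_lipids) < f).astype(np.int8)
    angles = rng.uniform(0, 2 * np.pi, spec.n_lipids)
    jitter = _JitterState(rng, (spec.n_lipids, 8))
    frames: list[BeadFrame] = []
    labels = np.empty((spec.n_frames, spec.n_lipids), dtype=np.int8)
    for fi in range(spec.n_frames):
        if fi > 0:
            lab = _advance_labels(lab, spec, neigh, rng)
            jitter.advance()
        labels[fi] = lab
        frames.append(_build_frame(spec, lab, nx, ny, neigh,
                                   jitter.state, angles, time=10.0 * fi))
    return frames, labels


def generate_ff_ensemble_ladder(
        reference_spec: SyntheticSpec,
        perturbations: Sequence[Mapping[str, float]],
        seed: int = 0,
) -> dict[str, tuple[list[BeadFrame], np.ndarray]]:
    """Named ensembles differing from the reference by increasing structural
    perturbation (delta APL and/or delta noise on the liquid phase).

    Returns {"reference": ..., "pert_00": ..., ...} in perturbation order;
    each value is (frames, labels).
    """
    if len(perturbations) < 2:
        raise ConfigurationError("need >= 2 perturbations for a ladder")
    seeds = np.random.SeedSequence(seed).spawn(len(perturbations) + 1)

    def child(spec, ss):
        return replace(spec, seed=int(ss.generate_state(1)[0] % (2**31 - 1)))

    out = {"reference": generate_trajectory(child(reference_spec, seeds[0]))}
    for i, pert in enumerate(perturbations):
        spec = replace(
            reference_spec,
            apl_liquid=reference_spec.apl_liquid + float(pert.get("dapl", 0.0)),
            noise_liquid=reference_spec.noise_liquid
            + float(pert.get("dnoise", 0.0)),
        )
        out[f"pert_{i:02d}"] = generate_trajectory(child(spec, seeds[i + 1]))
    return out
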