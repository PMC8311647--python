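"""Unified 4-site lipid bead representation.

Every downstream analysis works on the same reduced picture of a bilayer:
each lipid is replaced by four sites — charged head group (HEAD), phosphate
group (PHOS), and the two alkyl tails (TAIL1, TAIL2) — each defined as the
mass-weighted center of a named group of atoms/beads. This makes all-atom,
united-atom, and coarse-grained trajectories directly comparable: after
mapping, a frame is just an (n_lipids, 4, 3) coordinate array plus its
periodic box.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError, MappingError

#: Fixed site order along axis 1 of ``BeadFrame.coords``.
SITE_LABELS: tuple[str, ...] = ("HEAD", "PHOS", "TAIL1", "TAIL2")
#: Index of the phosphate site (the SOAP center) in ``SITE_LABELS``.
PHOS = SITE_LABELS.index("PHOS")

UPPER, LOWER = 0, 1
RESOLUTIONS = ("AA", "UA", "CG")


@dataclass(frozen=True)
class LipidTopologyMap:
    """Which atoms/beads of one force field form the four unified sites."""

    ff_name: str
    resolution: str
    site_defs: Mapping[str, tuple[str, ...]]
    lipid_selector: str = "all"

    def __post_init__(self) -> None:
        if self.resolution not in RESOLUTIONS:
            raise ConfigurationError(
                f"resolution must be one of {RESOLUTIONS}, got {self.resolution!r}")
        missing = [s for s in SITE_LABELS if s not in self.site_defs]
        if missing:
            raise ConfigurationError(f"missing site definition(s): {missing}")
        unknown = [s for s in self.site_defs if s not in SITE_LABELS]
        if unknown:
            raise ConfigurationError(f"unknown site label(s): {unknown}")
        for label, members in self.site_defs.items():
            if len(members) == 0:
                raise ConfigurationError(f"site {label} has no member atoms")

    @property
    def members(self) -> tuple[tuple[str, ...], ...]:
        """Member-name tuples in canonical site order."""
        return tuple(tuple(self.site_defs[s]) for s in SITE_LABELS)


def build_mapping(config) -> LipidTopologyMap:
    """Build and validate a :class:`LipidTopologyMap`.

    ``config`` may be a dict, a YAML string, or a path to a YAML file with
    keys ``ff_name``, ``resolution``, ``sites`` (label -> member names) and
    optionally ``lipid_selector``.
    """
    if isinstance(config, (str, Path)):
        p = Path(config)
        text = p.read_text() if p.exists() else str(config)
        config = yaml.safe_load(text)
    if not isinstance(config, Mapping):
        raise ConfigurationError("mapping config must be a mapping/YAML document")
    try:
        sites_raw = config["sites"]
    except KeyError:
        raise ConfigurationError("mapping config lacks a 'sites' section") from None
    if not isinstance(sites_raw, Mapping):
        raise ConfigurationError("'sites' must map site labels to member names")
    seen: dict[str, tuple[str, ...]] = {}
    for label, members in sites_raw.items():
        lab = str(label).upper()
        if lab in seen:
            raise ConfigurationError(f"duplicate site label: {lab}")
        if isinstance(members, str):
            members = [members]
        seen[lab] = tuple(str(m) for m in members)
    return LipidTopologyMap(
        ff_name=str(config.get("ff_name", "unnamed")),
        resolution=str(config.get("resolution", "CG")).upper(),
        site_defs=seen,
        lipid_selector=str(config.get("lipid_selector", "all")),
    )


@dataclass
class BeadFrame:
    """One snapshot of the unified bead representation.

    coords : (n_lipids, 4, 3) in nm, site order ``SITE_LABELS``;
    box : (Lx, Ly, Lz) in nm; the bilayer is periodic in x and y only;
    leaflet : per-lipid UPPER/LOWER assignment; time in ns.
    """

    coords: np.ndarray
    box: np.ndarray
    time: float = 0.0
    leaflet: np.ndarray | None = None
    periodic: tuple[bool, bool, bool] = (True, True, False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64).reshape(3)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (4, 3):
            raise MappingError(
                f"coords must have shape (n_lipids, 4, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise MappingError("a BeadFrame needs at least one lipid")
        if not np.all(np.isfinite(self.coords)):
            raise MappingError("non-finite coordinates in BeadFrame")
        if not np.all(self.box > 0):
            raise MappingError(f"box edges must be positive, got {self.box}")
        if self.leaflet is None:
            self.leaflet = assign_leaflets(self.coords)
        self.leaflet = np.asarray(self.leaflet, dtype=np.int8).reshape(-1)
        if self.leaflet.shape[0] != self.coords.shape[0]:
            raise MappingError("leaflet assignment must cover all lipids")

    @property
    def n_lipids(self) -> int:
        return self.coords.shape[0]

    @property
    def phos(self) -> np.ndarray:
        """(n_lipids, 3) phosphate-site coordinates."""
        return self.coords[:, PHOS, :]


def assign_leaflets(coords: np.ndarray) -> np.ndarray:
    """UPPER/LOWER by the sign of PHOS z relative to the bilayer midplane
    (mean phosphate z of the frame)."""
    z = np.asarray(coords)[:, PHOS, 2]
    mid = z.mean()
    return np.where(z >= mid, UPPER, LOWER).astype(np.int8)


def _unwrap_minimum_image(positions: np.ndarray, anchor: np.ndarray,
                          box: np.ndarray, periodic: Sequence[bool]) -> np.ndarray:
    """Shift each position by whole box vectors so it lies within half a box
    of ``anchor`` along every periodic axis."""
    out = positions.copy()
    for ax in range(3):
        if not periodic[ax]:
            continue
        d = out[:, ax] - anchor[ax]
        out[:, ax] -= np.round(d / box[ax]) * box[ax]
    return out


def map_frame(
    positions: np.ndarray,
    names: Sequence[str],
    resids: np.ndarray,
    masses: np.ndarray,
    box: np.ndarray,
    mapping: LipidTopologyMap,
    *,
    time: float = 0.0,
    periodic: tuple[bool, bool, bool] = (True, True, True),
) -> BeadFrame:
    """Reduce one raw frame (nm units) to a :class:`BeadFrame`.

    Each site is the mass-weighted mean of its member atoms, after
    minimum-image unwrapping of the residue relative to its first member
    atom; for single-member (CG) sites this is just the bead position.
    """
    positions = np.asarray(positions, dtype=np.float64)
    names = np.asarray(list(names))
    resids = np.asarray(resids)
    masses = np.asarray(masses, dtype=np.float64)
    box = np.asarray(box, dtype=np.float64).reshape(3)

    uniq = np.unique(resids)
    coords = np.empty((uniq.size, 4, 3))
    for i, rid in enumerate(uniq):
        sel = resids == rid
        res_pos, res_names, res_mass = positions[sel], names[sel], masses[sel]
        anchor = None
        for j, members in enumerate(mapping.members):
            idx = []
            for name in members:
                hits = np.nonzero(res_names == name)[0]
                if hits.size == 0:
                    raise MappingError(
                        f"residue {rid}: member atom {name!r} of site "
                        f"{SITE_LABELS[j]} not found")
                idx.extend(hits.tolist())
            pts = res_pos[idx]
            if anchor is None:
                anchor = pts[0]
            pts = _unwrap_minimum_image(pts, anchor, box, periodic)
            w = res_mass[idx]
            if not np.all(np.isfinite(w)) or w.sum() <= 0:
                w = np.ones_like(w)      # unknown masses -> geometric center
            coords[i, j] = (pts * w[:, None]).sum(axis=0) / w.sum()
    return BeadFrame(coords=coords, box=box, time=time)


def map_universe(universe, mapping: LipidTopologyMap,
                 *, stride: int = 1) -> Iterator[BeadFrame]:
    """Map an MDAnalysis Universe trajectory to BeadFrames (nm, ns).

    MDAnalysis reports lengths in Angstrom and times in ps; both are
    converted here.
    """
    group = universe.select_atoms(mapping.lipid_selector)
    if len(group) == 0:
        raise MappingError(
            f"lipid selector {mapping.lipid_selector!r} matched no atoms")
    for ts in universe.trajectory[::stride]:
        box = np.asarray(ts.dimensions[:3], dtype=np.float64) / 10.0
        masses = getattr(group, "masses", None)
        if masses is None or not np.all(np.isfinite(masses)) or masses.sum() == 0:
            masses = np.ones(len(group))
        yield map_frame(
            group.positions / 10.0,
            group.names,
            group.resids,
            masses,
            box,
            mapping,
            time=float(ts.time) / 1000.0,
        )
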