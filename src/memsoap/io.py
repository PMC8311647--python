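"""File formats: HDF5 bead/spectrum stores, GRO and extended-XYZ writers.

The HDF5 bead store holds one trajectory: datasets ``coords``
(n_frames, n_lipids, 4, 3), ``box`` (n_frames, 3), ``time`` (n_frames),
``leaflet`` (n_lipids) and a ``labels`` dataset when ground truth exists.
The spectrum store holds ``spectra`` (n_frames, n_lipids, D) with the SOAP
parameterization serialized into attributes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .errors import IncompatibilityError
from .mapping import SITE_LABELS, BeadFrame
from .soap import SoapParams

__all__ = [
    "write_bead_store",
    "read_bead_store",
    "write_spectra_store",
    "read_spectra_store",
    "write_gro",
    "write_extended_xyz",
]


def write_bead_store(path, frames: Sequence[BeadFrame],
                     labels: np.ndarray | None = None) -> None:
    frames = list(frames)
    coords = np.stack([f.coords for f in frames])
    with h5py.File(path, "w") as h5:
        h5.create_dataset("coords", data=coords, compression="gzip")
        h5.create_dataset("box", data=np.stack([f.box for f in frames]))
        h5.create_dataset("time", data=np.array([f.time for f in frames]))
        h5.create_dataset("leaflet", data=frames[0].leaflet)
        if labels is not None:
            h5.create_dataset("labels", data=np.asarray(labels, dtype=np.int8))
        h5.attrs["periodic"] = frames[0].periodic
        h5.attrs["site_order"] = ",".join(SITE_LABELS)


def read_bead_store(path) -> tuple[list[BeadFrame], np.ndarray | None]:
    with h5py.File(path, "r") as h5:
        coords = h5["coords"][()]
        box = h5["box"][()]
        time = h5["time"][()]
        leaflet = h5["leaflet"][()]
        labels = h5["labels"][()] if "labels" in h5 else None
    frames = [BeadFrame(coords=coords[i], box=box[i], time=float(time[i]),
                        leaflet=leaflet)
              for i in range(coords.shape[0])]
    return frames, labels


def write_spectra_store(path, spectra: np.ndarray, params: SoapParams,
                        times: np.ndarray | None = None) -> None:
    arr = np.asarray(spectra)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise IncompatibilityError(
            "spectra must be (n_frames, n_lipids, D) or (n_lipids, D)")
    with h5py.File(path, "w") as h5:
        h5.create_dataset("spectra", data=arr, compression="gzip")
        if times is not None:
            h5.create_dataset("time", data=np.asarray(times))
        h5.attrs["params"] = json.dumps(dataclasses.asdict(params))


def read_spectra_store(path) -> tuple[np.ndarray, SoapParams]:
    with h5py.File(path, "r") as h5:
        arr = h5["spectra"][()]
        raw = json.loads(h5.attrs["params"])
    raw["species"] = tuple(raw["species"])
    return arr, SoapParams(**raw)


_GRO_NAMES = ("HD", "PO", "T1", "T2")


def write_gro(path, frame: BeadFrame, title: str = "memsoap bilayer") -> None:
    """Write one bead frame as a GRO file (nm), one residue per lipid."""
    lines = [title, f"{frame.n_lipids * 4:5d}"]
    atom = 0
    for i in range(frame.n_lipids):
        for j, name in enumerate(_GRO_NAMES):
            atom += 1
            x, y, z = frame.coords[i, j]
            lines.append(f"{(i + 1) % 100000:5d}{'LIP':<5s}{name:>5s}"
                         f"{atom % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}")
    lines.append(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_extended_xyz(path, frames: Sequence[BeadFrame]) -> None:
    """Extended-XYZ trajectory (nm): Lattice + pbc in the comment line."""
    with open(path, "w") as fh:
        for fr in frames:
            fh.write(f"{fr.n_lipids * 4}\n")
            lx, ly, lz = fr.box
            fh.write(
                f'Lattice="{lx} 0 0 0 {ly} 0 0 0 {lz}" '
                f'Properties=species:S:1:pos:R:3 pbc="T T F" '
                f"Time={fr.time}\n")
            for i in range(fr.n_lipids):
                for j, name in enumerate(_GRO_NAMES):
                    x, y, z = fr.coords[i, j]
                    fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")
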