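"""Ensemble-averaged SOAP kernel distance between force fields.

A force field's bilayer ensemble is summarized by the arithmetic mean of the
raw per-lipid power spectra over lipids and equilibrium frames. Two ensembles
are compared with the normalized linear kernel

    K(p1, p2) = p1 . p2 / (|p1| |p2|)        in [0, 1] for these spectra,

and the induced metric

    d(p1, p2) = sqrt(2 - 2 K(p1, p2)),

which is the Euclidean distance between the unit-normalized vectors. The
all-pairs distance matrix is then summarized by average-linkage hierarchical
clustering and a 2D metric-MDS (SMACOF) embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy
from sklearn.manifold import MDS

from .errors import DegenerateEnvironmentError, IncompatibilityError
from .soap import ENSEMBLE_AVERAGE, PowerSpectrum, SoapParams

__all__ = [
    "DistanceMatrix",
    "EmbeddingResult",
    "ensemble_average",
    "soap_kernel",
    "soap_distance",
    "distance_matrix",
    "hierarchical_cluster",
    "mds_embed",
]


@dataclass
class DistanceMatrix:
    """Symmetric matrix of ensemble SOAP distances with system labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise IncompatibilityError(
                f"distance matrix shape {self.values.shape} does not match "
                f"{n} labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise IncompatibilityError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise IncompatibilityError("distance matrix diagonal must be zero")
        if self.values.min() < -1e-12 or self.values.max() > 2.0 + 1e-12:
            raise IncompatibilityError("SOAP distances must lie in [0, 2]")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class EmbeddingResult:
    """2D MDS coordinates of the systems plus the final SMACOF stress."""

    labels: list[str]
    coords: np.ndarray
    stress: float
    seed: int


def _check_compatible(spectra: Sequence[PowerSpectrum]) -> SoapParams:
    params = spectra[0].params
    for s in spectra[1:]:
        if s.params != params:
            raise IncompatibilityError(
                "spectra computed with different SOAP parameters cannot be "
                "combined")
    return params


def ensemble_average(spectra: Iterable[PowerSpectrum] | np.ndarray,
                     params: SoapParams | None = None,
                     provenance: dict | None = None) -> PowerSpectrum:
    """Component-wise mean of raw (unnormalized) spectra.

    Accepts either PowerSpectrum objects or a raw (N, D) array plus params.
    Normalization happens later, inside the kernel — the ensemble mean is kept
    on the raw scale so that lipids and frames contribute with equal weight.
    """
    if isinstance(spectra, np.ndarray):
        if params is None:
            raise IncompatibilityError("params required with a raw array")
        arr = np.asarray(spectra, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[0] < 1:
            raise IncompatibilityError("need a non-empty (N, D) array")
    else:
        spectra = list(spectra)
        if not spectra:
            raise IncompatibilityError("need at least one spectrum to average")
        params = _check_compatible(spectra)
        arr = np.stack([s.vector for s in spectra])
    return PowerSpectrum(vector=arr.mean(axis=0), params=params,
                         center_kind=ENSEMBLE_AVERAGE,
                         provenance=provenance or {"n_spectra": arr.shape[0]})


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise DegenerateEnvironmentError("zero spectrum has no direction")
    return v / n


def soap_kernel(p1: PowerSpectrum, p2: PowerSpectrum) -> float:
    """Normalized linear kernel of two spectra (cosine similarity)."""
    _check_compatible([p1, p2])
    return float(np.dot(_unit(p1.vector), _unit(p2.vector)))


def soap_distance(p1: PowerSpectrum, p2: PowerSpectrum) -> float:
    """d = sqrt(2 - 2 K); the Euclidean metric on unit-normalized spectra."""
    k = soap_kernel(p1, p2)
    return float(np.sqrt(max(0.0, 2.0 - 2.0 * k)))


def distance_matrix(ensembles: Mapping[str, PowerSpectrum]) -> DistanceMatrix:
    """All-pairs SOAP distances between named ensemble-average spectra."""
    labels = list(ensembles)
    if len(labels) < 2:
        raise IncompatibilityError("need at least 2 ensembles to compare")
    _check_compatible([ensembles[k] for k in labels])
    units = np.stack([_unit(ensembles[k].vector) for k in labels])
    gram = np.clip(units @ units.T, -1.0, 1.0)
    d = np.sqrt(np.maximum(0.0, 2.0 - 2.0 * gram))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(labels=labels, values=d)


def hierarchical_cluster(m: DistanceMatrix):
    """Average-linkage agglomerative dendrogram of the distance matrix.

    Returns (linkage_matrix, leaf_order) in scipy's linkage format; leaf
    order is the deterministic dendrogram ordering.
    """
    n = len(m.labels)
    iu = np.triu_indices(n, k=1)
    condensed = m.values[iu]
    Z = hierarchy.linkage(condensed, method="average")
    order = hierarchy.leaves_list(Z)
    return Z, [m.labels[i] for i in order]


def mds_embed(m: DistanceMatrix, seed: int = 0, *,
              n_init: int = 8, max_iter: int = 500) -> EmbeddingResult:
    """2D metric-MDS (SMACOF) of the distance matrix; best of n_init starts."""
    n = len(m.labels)
    if n < 3:
        raise IncompatibilityError("MDS needs at least 3 systems")
    mds = MDS(n_components=2, metric="precomputed", metric_mds=True,
              init="random", n_init=n_init, max_iter=max_iter,
              random_state=int(seed), eps=1e-9, n_jobs=1)
    coords = mds.fit_transform(m.values)
    return EmbeddingResult(labels=list(m.labels), coords=coords,
                           stress=float(mds.stress_), seed=int(seed))
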