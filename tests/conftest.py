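"""Shared fixtures: small synthetic frames and spectra."""

import numpy as np
import pytest

from memsoap.mapping import BeadFrame
from memsoap.soap import SoapParams


def random_bilayer_frame(rng: np.random.Generator, n_lipids: int = 20,
                         box_xy: float = 5.0) -> BeadFrame:
    """A loose random two-leaflet frame (no lattice), nm units."""
    n = n_lipids
    coords = np.zeros((n, 4, 3))
    xy = rng.uniform(0, box_xy, size=(n, 2))
    sgn = np.where(np.arange(n) < n // 2, 1.0, -1.0)
    z = sgn * 1.9 + rng.normal(0, 0.05, n)
    coords[:, 1, :2] = xy
    coords[:, 1, 2] = z
    coords[:, 0, :2] = xy + rng.normal(0, 0.05, (n, 2))
    coords[:, 0, 2] = z + sgn * 0.4
    for t in (2, 3):
        coords[:, t, :2] = xy + rng.normal(0, 0.15, (n, 2))
        coords[:, t, 2] = sgn * 0.5 + rng.normal(0, 0.05, n)
    coords[..., 0] %= box_xy
    coords[..., 1] %= box_xy
    return BeadFrame(coords=coords, box=[box_xy, box_xy, 10.0])


@pytest.fixture(scope="session")
def small_params() -> SoapParams:
    """Reduced-resolution descriptor for fast tests."""
    return SoapParams(n_max=4, l_max=4, sigma=0.12, r_cut=1.2)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
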