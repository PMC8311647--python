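"""Real spherical harmonics evaluated by stable upward recurrence.

The density expansion needs every real harmonic up to degree ``l_max`` for
large batches of neighbor directions, so the associated Legendre functions are
generated in one vectorized sweep instead of per-(l, m) library calls.
Normalization is the orthonormal ("quantum") one: the returned basis satisfies
``integral over the sphere of Y_lm * Y_l'm' = delta``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["real_sph_harm", "lm_index", "n_lm"]


def n_lm(l_max: int) -> int:
    """Number of real harmonics with degree <= l_max."""
    return (l_max + 1) ** 2


def lm_index(l: int, m: int) -> int:
    """Flat index of the real harmonic (l, m), m in [-l, l]."""
    return l * l + l + m


def real_sph_harm(l_max: int, unit_vectors: np.ndarray) -> np.ndarray:
    """Evaluate all real spherical harmonics up to ``l_max``.

    Parameters
    ----------
    l_max:
        Maximum degree.
    unit_vectors:
        Array of shape (N, 3); rows need not be normalized (they are
        normalized internally). Rows of zero length are treated as the +z
        direction, for which only the m = 0 harmonics are nonzero anyway.

    Returns
    -------
    ndarray of shape (N, (l_max + 1)**2), ordered by ``lm_index``:
    for each l the columns run m = -l ... +l, with m < 0 the sine and
    m > 0 the cosine combinations (times sqrt(2)).
    """
    v = np.asarray(unit_vectors, dtype=np.float64)
    if v.ndim != 2 or v.shape[1] != 3:
        raise ValueError("unit_vectors must have shape (N, 3)")
    r = np.linalg.norm(v, axis=1)
    safe = np.where(r > 0, r, 1.0)
    x, y, z = (v[:, i] / safe for i in range(3))
    z = np.where(r > 0, z, 1.0)  # degenerate rows -> +z

    ct = np.clip(z, -1.0, 1.0)                       # cos(theta)
    st = np.sqrt(np.maximum(0.0, 1.0 - ct * ct))     # sin(theta)
    rho = np.hypot(x, y)
    # azimuth unit components; arbitrary (1, 0) on the pole where st = 0
    cphi = np.where(rho > 0, x / np.where(rho > 0, rho, 1.0), 1.0)
    sphi = np.where(rho > 0, y / np.where(rho > 0, rho, 1.0), 0.0)

    n = v.shape[0]
    out = np.empty((n, n_lm(l_max)), dtype=np.float64)

    # Normalized associated Legendre P~_l^m including Condon-Shortley phase:
    #   P~_0^0 = sqrt(1 / 4pi)
    #   P~_m^m = -sqrt((2m + 1) / 2m) * sin(theta) * P~_{m-1}^{m-1}
    #   P~_{m+1}^m = sqrt(2m + 3) * cos(theta) * P~_m^m
    #   P~_l^m = a_l^m (cos(theta) P~_{l-1}^m - b_{l-1}^m P~_{l-2}^m)
    pmm = np.full(n, np.sqrt(1.0 / (4.0 * np.pi)))
    # cos(m phi), sin(m phi) by angle-addition recurrence
    cm = np.ones(n)
    sm = np.zeros(n)
    sqrt2 = np.sqrt(2.0)

    def emit(l: int, m: int, plm: np.ndarray) -> None:
        if m == 0:
            out[:, lm_index(l, 0)] = plm
        else:
            # real combinations sqrt(2) * Re/Im of the complex Y_lm
            # (Condon-Shortley phase carried inside P~_l^m)
            out[:, lm_index(l, m)] = sqrt2 * plm * cm
            out[:, lm_index(l, -m)] = sqrt2 * plm * sm

    for m in range(l_max + 1):
        if m > 0:
            pmm = -np.sqrt((2.0 * m + 1.0) / (2.0 * m)) * st * pmm
            cm, sm = cm * cphi - sm * sphi, sm * cphi + cm * sphi
        emit(m, m, pmm)
        if m + 1 <= l_max:
            p_prev2, p_prev1 = pmm, np.sqrt(2.0 * m + 3.0) * ct * pmm
            emit(m + 1, m, p_prev1)
            for l in range(m + 2, l_max + 1):
                a = np.sqrt((4.0 * l * l - 1.0) / (l * l - m * m))
                b = np.sqrt(((l - 1.0) ** 2 - m * m)
                            / (4.0 * (l - 1.0) ** 2 - 1.0))
                p_prev2, p_prev1 = p_prev1, a * (ct * p_prev1 - b * p_prev2)
                emit(l, m, p_prev1)
    return out
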