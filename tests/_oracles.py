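"""Independent reference implementations used only as test oracles.

Deliberately share no numerical machinery with the package: the SOAP oracle
integrates the density-expansion coefficients by direct 3D product quadrature
(Gauss-Legendre radially and in cos(theta), uniform in phi) with scipy's
spherical harmonics, orthonormalizes the radial basis with a matrix square
root instead of the package's eigendecomposition, and reimplements the
power-spectrum flattening as explicit loops. The linkage oracle is a naive
O(n^3) average-linkage agglomerator.
"""

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.linalg import inv, sqrtm
from scipy.special import sph_harm_y

from memsoap.mapping import BeadFrame


def _oracle_real_Y(l_max: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real harmonics in the package's documented convention:
    m = 0 -> Re(Y); m > 0 -> sqrt(2) Re(Y_lm); m < 0 -> sqrt(2) Im(Y_l|m|)."""
    cols = []
    for l in range(l_max + 1):
        block = np.empty((theta.size, 2 * l + 1))
        for m in range(0, l + 1):
            y = sph_harm_y(l, m, theta, phi)
            if m == 0:
                block[:, l] = y.real
            else:
                block[:, l + m] = np.sqrt(2.0) * y.real
                block[:, l - m] = np.sqrt(2.0) * y.imag
        cols.append(block)
    return np.concatenate(cols, axis=1)


def _oracle_radial_basis(n_max: int, r_cut: float, r: np.ndarray) -> np.ndarray:
    """Orthonormalized polynomial basis; overlap integrated numerically."""
    x, w = leggauss(400)
    rq = (x + 1) / 2 * r_cut
    wq = w * r_cut / 2
    phi_q = np.stack([(r_cut - rq) ** (k + 2) for k in range(1, n_max + 1)])
    S = np.einsum("q,iq,jq->ij", wq * rq**2, phi_q, phi_q)
    W = inv(sqrtm(S))
    phi_r = np.stack([(np.clip(r_cut - r, 0, None)) ** (k + 2)
                      for k in range(1, n_max + 1)])
    return np.real(W) @ phi_r


def soap_vector_numeric(frame: BeadFrame, center: int, n_max: int, l_max: int,
                        sigma: float, r_cut: float,
                        n_r: int = 320, n_theta: int = 48,
                        n_phi: int = 96) -> np.ndarray:
    """Brute-force SOAP power spectrum of one lipid environment."""
    box = frame.box
    c0 = frame.coords[center, 1]
    # neighbors within the cutoff, explicit xy images
    sites = frame.coords.reshape(-1, 3)
    species = np.tile(np.arange(4), frame.n_lipids)
    shifts = np.array([(i * box[0], j * box[1], 0.0)
                       for i in (-1, 0, 1) for j in (-1, 0, 1)])
    tiled = (sites[None] + shifts[:, None]).reshape(-1, 3)
    tsp = np.tile(species, 9)
    rel = tiled - c0
    keep = (rel**2).sum(axis=1) < r_cut**2
    rel, tsp = rel[keep], tsp[keep]

    xr, wr = leggauss(n_r)
    r = (xr + 1) / 2 * r_cut
    wr = wr * r_cut / 2
    xt, wt = leggauss(n_theta)
    phis = np.arange(n_phi) * 2 * np.pi / n_phi
    ct = xt
    st = np.sqrt(1 - ct**2)
    dirs = np.stack([
        st[:, None] * np.cos(phis)[None, :],
        st[:, None] * np.sin(phis)[None, :],
        np.broadcast_to(ct[:, None], (n_theta, n_phi)),
    ], -1).reshape(-1, 3)
    theta_flat = np.arccos(np.clip(np.repeat(ct, n_phi), -1, 1))
    phi_flat = np.tile(phis, n_theta)
    Y = _oracle_real_Y(l_max, theta_flat, phi_flat)
    w_ang = np.repeat(wt, n_phi) * (2 * np.pi / n_phi)
    g = _oracle_radial_basis(n_max, r_cut, r)            # (n, n_r)
    a = 1.0 / (2 * sigma**2)
    n_lm = (l_max + 1) ** 2
    pts = r[:, None, None] * dirs[None, :, :]            # (n_r, n_ang, 3)

    c = np.zeros((4, n_max, n_lm))
    for s in range(4):
        nb = rel[tsp == s]
        if nb.shape[0] == 0:
            continue
        rho = np.zeros((n_r, dirs.shape[0]))
        for j in range(nb.shape[0]):
            rho += np.exp(-a * ((pts - nb[j]) ** 2).sum(-1))
        ang = rho @ (Y * w_ang[:, None])                 # (n_r, n_lm)
        c[s] = np.einsum("q,nq,ql->nl", wr * r**2, g, ang)

    out = []
    for s in range(4):
        for t in range(s, 4):
            for l in range(l_max + 1):
                pref = np.pi * np.sqrt(8.0 / (2 * l + 1))
                lo, hi = l * l, (l + 1) ** 2
                for na in range(n_max):
                    for nb_ in range(na if s == t else 0, n_max):
                        val = pref * np.dot(c[s, na, lo:hi], c[t, nb_, lo:hi])
                        if not (s == t and na == nb_):
                            val *= np.sqrt(2.0)
                        out.append(val)
    return np.asarray(out)


def average_linkage_naive(dist: np.ndarray) -> list[float]:
    """Merge heights of naive average-linkage agglomeration (sorted)."""
    clusters = [[i] for i in range(dist.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([dist[a, b] for a in clusters[i]
                             for b in clusters[j]])
                if d < best[0]:
                    best = (d, (i, j))
        d, (i, j) = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return sorted(heights)
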