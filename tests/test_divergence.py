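"""Subsampling, PCA reduction, TwoNN, grid densities, Jensen-Shannon."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from memsoap.divergence import (GriddedDensity, GridSpec, correlate_metrics,
                                jensen_shannon, knn_density_on_grid,
                                pca_reduce, subsample_spectra,
                                twonn_intrinsic_dimension)
from memsoap.errors import (IncompatibilityError, InsufficientDataError)


class TestSubsample:
    def test_pooled_sample_count(self, rng):
        """128 spectra/frame x 100 frames x 3 systems = 38,400 spectra."""
        total = 0
        for s in range(3):
            frames = [rng.random((256, 8)) for _ in range(120)]
            sample = subsample_spectra(frames, 128, 100, seed=s)
            assert sample.shape == (12800, 8)
            total += sample.shape[0]
        assert total == 38400

    def test_full_frame_is_deterministic(self, rng):
        frames = [rng.random((64, 4)) for _ in range(5)]
        a = subsample_spectra(frames, 64, 5, seed=1)
        b = subsample_spectra(frames, 64, 5, seed=99)
        np.testing.assert_array_equal(a, b)

    def test_same_seed_same_sample(self, rng):
        frames = [rng.random((64, 4)) for _ in range(5)]
        a = subsample_spectra(frames, 16, 5, seed=7)
        b = subsample_spectra(frames, 16, 5, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_oversampling_rejected(self, rng):
        frames = [rng.random((8, 4))]
        with pytest.raises(InsufficientDataError):
            subsample_spectra(frames, 9, 1, seed=0)
        with pytest.raises(InsufficientDataError):
            subsample_spectra(frames, 4, 2, seed=0)


class TestPCA:
    def test_planar_data_fully_explained(self, rng):
        basis = rng.normal(size=(2, 10))
        data = rng.normal(size=(500, 2)) @ basis
        red = pca_reduce(data, 2)
        assert np.sum(red.explained_variance_ratio) == pytest.approx(
            1.0, abs=1e-9)

    def test_shared_basis_across_systems(self, rng):
        sys_a = rng.normal(size=(300, 6))
        sys_b = rng.normal(size=(300, 6)) + 2.0
        red = pca_reduce({"a": sys_a, "b": sys_b}, 5)
        np.testing.assert_array_equal(red["a"].basis, red["b"].basis)
        assert red["a"].points.shape == (300, 5)

    def test_duplicated_system_projects_identically(self, rng):
        x = rng.normal(size=(200, 6))
        red = pca_reduce({"a": x, "b": x.copy()}, 3)
        np.testing.assert_allclose(red["a"].points, red["b"].points)

    def test_isotropic_variances_roughly_equal(self, rng):
        red = pca_reduce(rng.normal(size=(20000, 5)), 5)
        ev = red.explained_variance
        assert ev.max() / ev.min() < 1.15

    def test_rank_error(self, rng):
        t = rng.normal(size=(100, 1))
        data = np.hstack([t, 2 * t, -t])            # rank 1
        with pytest.raises(InsufficientDataError, match="rank"):
            pca_reduce(data, 2)

    def test_matches_svd_oracle(self, rng):
        """Covariance-eigendecomposition PCA agrees with a direct SVD."""
        x = rng.normal(size=(400, 7)) * np.arange(1, 8)
        red = pca_reduce(x, 3)
        xc = x - x.mean(axis=0)
        _, sv, vt = np.linalg.svd(xc, full_matrices=False)
        for i in range(3):
            assert abs(np.dot(red.basis[i], vt[i])) == pytest.approx(
                1.0, abs=1e-8)
        np.testing.assert_allclose(red.explained_variance,
                                   sv[:3] ** 2 / x.shape[0], rtol=1e-8)


class TestTwoNN:
    def test_uniform_5d_hypercube(self, rng):
        est = twonn_intrinsic_dimension(rng.uniform(size=(5000, 5)))
        assert 4.2 <= est <= 5.8

    def test_line_embedded_in_10d(self, rng):
        t = rng.uniform(size=(2000, 1))
        data = t @ rng.normal(size=(1, 10))
        data += rng.normal(0, 1e-9, data.shape)
        est = twonn_intrinsic_dimension(data)
        assert 0.8 <= est <= 1.3

    def test_duplicates_dropped_with_warning(self, rng):
        pts = rng.uniform(size=(400, 3))
        pts = np.vstack([pts, pts[:50]])
        with pytest.warns(UserWarning, match="duplicate"):
            est = twonn_intrinsic_dimension(pts)
        assert np.isfinite(est)

    def test_too_few_points(self, rng):
        with pytest.raises(InsufficientDataError):
            twonn_intrinsic_dimension(rng.uniform(size=(50, 3)))

    def test_estimate_tightens_with_sample_size(self, rng):
        """Spread of repeated estimates shrinks as n grows (consistency)."""
        spreads = []
        for n in (300, 3000):
            ests = [twonn_intrinsic_dimension(rng.uniform(size=(n, 3)))
                    for _ in range(5)]
            spreads.append(np.std(ests))
        assert spreads[1] < spreads[0]


class TestGridDensity:
    def test_gaussian_total_variation(self, rng):
        pts = rng.normal(size=(100000, 2))
        grid = GridSpec((-4, -4), (4, 4), (40, 40))
        dens = knn_density_on_grid(pts, grid, k_neighbors=128)
        edges = np.linspace(-4, 4, 41)
        p1 = np.diff(norm.cdf(edges))
        true = np.outer(p1, p1)
        true /= true.sum()
        tv = 0.5 * np.abs(dens.mass - true).sum()
        assert tv < 0.05

    def test_point_mass_peaks_at_its_cell(self, rng):
        """A near-degenerate cluster puts its largest mass in the containing
        cell (far cells inherit the neighbors' density without decay — an
        acknowledged limit of nearest-sample extrapolation — but the mode
        must sit on the cluster)."""
        pts = np.zeros((500, 2)) + rng.normal(0, 1e-9, (500, 2))
        grid = GridSpec((-1, -1), (1, 1), (11, 11))
        dens = knn_density_on_grid(pts, grid, k_neighbors=8)
        assert np.unravel_index(dens.mass.argmax(), dens.mass.shape) == (5, 5)
        assert dens.mass[5, 5] > 10 * np.median(dens.mass)

    def test_duplication_invariance(self, rng):
        """Duplicating every point leaves the normalized field unchanged when
        the neighbor counts scale with the duplication factor."""
        pts = rng.normal(size=(2000, 2))
        grid = GridSpec.from_data(pts, bins=10)
        a = knn_density_on_grid(pts, grid, k_neighbors=8,
                                extrapolation_neighbors=3)
        b = knn_density_on_grid(np.repeat(pts, 2, axis=0), k_neighbors=16,
                                grid=grid, extrapolation_neighbors=6)
        np.testing.assert_allclose(a.mass, b.mass, atol=1e-12)

    def test_empty_points_rejected(self):
        grid = GridSpec((-1,), (1,), (4,))
        with pytest.raises(InsufficientDataError):
            knn_density_on_grid(np.empty((0, 1)), grid)


def _dens(masses, grid=None):
    m = np.asarray(masses, dtype=float)
    grid = grid or GridSpec((0,), (1,), (m.size,))
    return GriddedDensity(grid=grid, mass=m / m.sum())


class TestJensenShannon:
    def test_self_divergence_zero(self, rng):
        p = _dens(rng.random(16) + 0.01)
        assert jensen_shannon(p, p) == 0.0

    def test_disjoint_supports(self):
        p = _dens([1, 1, 0, 0])
        q = _dens([0, 0, 1, 1])
        assert jensen_shannon(p, q) == pytest.approx(np.log(2.0), abs=1e-12)

    def test_two_cell_worked_example(self):
        """p = (0.5, 0.5), q = (0.9, 0.1):
        KL(p||m) = 0.087177, KL(q||m) = 0.116322 -> JSD = 0.101749 nats."""
        p = _dens([0.5, 0.5])
        q = _dens([0.9, 0.1])
        assert jensen_shannon(p, q) == pytest.approx(0.101749, abs=1e-3)

    def test_symmetry_exact(self, rng):
        p = _dens(rng.random(32))
        q = _dens(rng.random(32))
        assert jensen_shannon(p, q) == jensen_shannon(q, p)

    def test_grid_mismatch(self):
        p = _dens([1, 1])
        q = _dens([1, 1, 1])
        with pytest.raises(IncompatibilityError):
            jensen_shannon(p, q)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=5.0), min_size=6,
                max_size=6),
       st.lists(st.floats(min_value=0.0, max_value=5.0), min_size=6,
                max_size=6))
def test_jsd_bounds_property(u, v):
    if sum(u) == 0 or sum(v) == 0:
        return
    j = jensen_shannon(_dens(u), _dens(v))
    assert 0.0 <= j <= np.log(2.0)


class TestCorrelate:
    def test_perfect_linear(self):
        x = [0.1, 0.2, 0.3, 0.4]
        r, rho = correlate_metrics(x, [2 * v for v in x])
        assert r == pytest.approx(1.0)
        assert rho == pytest.approx(1.0)

    def test_anti_ordered(self):
        r, rho = correlate_metrics([1.0, 2.0, 3.0], [5.0, 4.0, 1.0])
        assert rho == pytest.approx(-1.0)

    def test_mapping_keys_must_match(self):
        with pytest.raises(IncompatibilityError):
            correlate_metrics({("a", "b"): 1.0, ("a", "c"): 2.0,
                               ("b", "c"): 3.0},
                              {("a", "b"): 1.0, ("a", "d"): 2.0,
                               ("b", "c"): 3.0})
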