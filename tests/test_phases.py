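"""PAMM-style clustering, phase assignment, kinetics, melting detection."""

import numpy as np
import pytest

from memsoap.errors import IncompatibilityError, InsufficientDataError
from memsoap.phases import (GEL, LIQUID, ClusterModel, LabelTrajectory,
                            assign_phase, detect_transition, pamm_cluster,
                            pool_and_reduce, population_curve,
                            transition_matrix)


def two_blob_data(rng, n=5000, frac=0.3, sep=10.0):
    lab = rng.random(n) < frac
    pts = np.where(lab[:, None], rng.normal(0, 1, (n, 2)) + [sep, 0],
                   rng.normal(0, 1, (n, 2)))
    return pts, lab.astype(int)


class TestPammCluster:
    def test_two_separated_blobs(self, rng):
        pts, lab = two_blob_data(rng)
        model = pamm_cluster(pts, seed=1)
        assert model.n_clusters == 2
        pred, _ = assign_phase(pts, model)
        acc = max((pred == lab).mean(), (pred == 1 - lab).mean())
        assert acc >= 0.99

    def test_single_blob_single_cluster(self, rng):
        model = pamm_cluster(rng.normal(size=(3000, 2)), seed=0)
        assert model.n_clusters == 1

    def test_weights_recovered(self, rng):
        pts, _ = two_blob_data(rng, n=5000, frac=0.3)
        model = pamm_cluster(pts, seed=2)
        assert model.n_clusters == 2
        w = np.sort(model.weights)
        assert w[0] == pytest.approx(0.3, abs=0.05)
        assert w[1] == pytest.approx(0.7, abs=0.05)

    def test_deterministic_given_seed(self, rng):
        pts, _ = two_blob_data(rng, n=2000)
        a = pamm_cluster(pts, seed=5)
        b = pamm_cluster(pts, seed=5)
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_too_few_points(self, rng):
        with pytest.raises(InsufficientDataError):
            pamm_cluster(rng.normal(size=(100, 2)))

    def test_identical_points_degenerate(self):
        with pytest.raises(InsufficientDataError):
            pamm_cluster(np.ones((600, 2)))

    def test_gel_is_the_denser_cluster(self, rng):
        """Tight blob (gel-like) vs broad blob: GEL maps to the tight one."""
        tight = rng.normal(0, 0.3, (2000, 2))
        broad = rng.normal(0, 1.5, (2000, 2)) + [8, 0]
        model = pamm_cluster(np.vstack([tight, broad]), seed=3)
        assert model.n_clusters == 2
        gel_mean = model.means[model.gel_cluster()]
        assert np.linalg.norm(gel_mean - [0, 0]) < np.linalg.norm(
            gel_mean - [8, 0])

    def test_packing_overrides_density_naming(self, rng):
        """With a packing observable (Voronoi-like areas), the low-area
        cluster is GEL regardless of KDE density."""
        pts, lab = two_blob_data(rng, n=3000)
        areas = np.where(lab == 1, 0.47, 0.64)
        model = pamm_cluster(pts, seed=4, member_packing=areas)
        pred, _ = assign_phase(pts, model)
        gel_id = model.gel_cluster()
        # the predicted-gel population must coincide with the low-area blob
        assert ((pred == gel_id) == (lab == 1)).mean() > 0.99


class TestAssignPhase:
    def _model(self):
        return ClusterModel(
            modes=np.array([[0.0, 0.0], [5.0, 0.0]]),
            weights=np.array([0.5, 0.5]),
            means=np.array([[0.0, 0.0], [5.0, 0.0]]),
            covariances=np.stack([np.eye(2), np.eye(2)]),
            labels_map={0: GEL, 1: LIQUID},
            bandwidth=np.ones(2))

    def test_point_at_mean_high_responsibility(self):
        lab, resp = assign_phase(np.array([[0.0, 0.0]]), self._model())
        assert lab[0] == 0
        assert resp[0, 0] > 0.99

    def test_equidistant_point_splits_evenly(self):
        lab, resp = assign_phase(np.array([[2.5, 0.0]]), self._model())
        assert resp[0, 0] == pytest.approx(0.5, abs=1e-9)
        assert resp[0, 1] == pytest.approx(0.5, abs=1e-9)

    def test_dimension_mismatch(self):
        with pytest.raises(IncompatibilityError):
            assign_phase(np.zeros((3, 5)), self._model())

    def test_held_out_points(self, rng):
        pts, lab = two_blob_data(rng, n=4000)
        model = pamm_cluster(pts[:2000], seed=1)
        pred, _ = assign_phase(pts[2000:], model)
        truth = lab[2000:]
        acc = max((pred == truth).mean(), (pred == 1 - truth).mean())
        assert acc >= 0.99


class TestPoolAndReduce:
    def test_shared_space_across_temperatures(self, rng):
        per_t = {273.0: rng.normal(size=(40, 30, 12)),
                 303.0: rng.normal(size=(40, 30, 12)) + 1.0,
                 333.0: rng.normal(size=(40, 30, 12)) + 2.0}
        reduced, basis = pool_and_reduce(per_t, k=5)
        assert basis.shape == (5, 12)
        for t, r in reduced.items():
            assert r.points.shape == (1200, 5)
            np.testing.assert_array_equal(r.basis, basis)

    def test_duplicated_temperature_identical_projection(self, rng):
        x = rng.normal(size=(100, 8))
        reduced, _ = pool_and_reduce({1.0: x, 2.0: x.copy()}, k=3)
        np.testing.assert_allclose(reduced[1.0].points, reduced[2.0].points)

    def test_rank2_data_lossless_with_k2(self, rng):
        basis = rng.normal(size=(2, 10))
        per_t = {1.0: rng.normal(size=(200, 2)) @ basis,
                 2.0: rng.normal(size=(200, 2)) @ basis}
        reduced, axes = pool_and_reduce(per_t, k=2)
        rec = reduced[1.0].points @ axes + reduced[1.0].mean
        np.testing.assert_allclose(rec, per_t[1.0], atol=1e-8)

    def test_mismatched_lengths(self, rng):
        with pytest.raises(IncompatibilityError):
            pool_and_reduce({1.0: rng.normal(size=(50, 8)),
                             2.0: rng.normal(size=(50, 9))}, k=2)


class TestTransitionMatrix:
    def test_constant_labels_identity(self):
        traj = LabelTrajectory(labels=np.zeros((10, 20), int),
                               temperature=300)
        tm = transition_matrix(traj, n_clusters=2)
        assert tm.matrix[0, 0] == pytest.approx(1.0)
        assert tm.undefined_rows[1]

    def test_strict_alternation(self):
        lab = np.tile([0, 1], (20, 1)).T[:, :5]   # A B A B ... per lipid
        lab = np.tile(np.array([[0], [1]] * 10), (1, 5))
        traj = LabelTrajectory(labels=lab, temperature=300)
        tm = transition_matrix(traj)
        assert tm.matrix[0, 1] == pytest.approx(1.0)
        assert tm.matrix[1, 0] == pytest.approx(1.0)

    def test_markov_rate_recovery(self, rng):
        """Planted p(gel->liquid) = 0.08 per step, 1152 lipids x 100 frames."""
        F, N, p = 100, 1152, 0.08
        lab = np.empty((F, N), dtype=int)
        lab[0] = (rng.random(N) < 0.5).astype(int)
        for t in range(1, F):
            flip = rng.random(N) < p
            lab[t] = np.where(flip, 1 - lab[t - 1], lab[t - 1])
        tm = transition_matrix(LabelTrajectory(labels=lab, temperature=300))
        assert tm.matrix[0, 1] == pytest.approx(p, abs=0.01)
        assert tm.matrix[1, 0] == pytest.approx(p, abs=0.01)

    def test_counts_conserve_events(self, rng):
        lab = (rng.random((30, 40)) < 0.5).astype(int)
        tm = transition_matrix(LabelTrajectory(labels=lab, temperature=1))
        assert tm.counts.sum() == 40 * 29

    def test_rows_sum_to_one(self, rng):
        lab = rng.integers(0, 3, size=(50, 10))
        tm = transition_matrix(LabelTrajectory(labels=lab, temperature=1))
        np.testing.assert_allclose(tm.matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_stationary_consistency(self, rng):
        """Long chain: stationary distribution of the recovered matrix
        matches the observed label fractions."""
        F, N = 2000, 200
        p01, p10 = 0.05, 0.15
        lab = np.empty((F, N), dtype=int)
        lab[0] = (rng.random(N) < p01 / (p01 + p10)).astype(int)
        for t in range(1, F):
            u = rng.random(N)
            lab[t] = np.where(lab[t - 1] == 0, (u < p01).astype(int),
                              (u >= p10).astype(int))
        tm = transition_matrix(LabelTrajectory(labels=lab, temperature=1))
        evals, evecs = np.linalg.eig(tm.matrix.T)
        pi = np.real(evecs[:, np.argmax(np.real(evals))])
        pi /= pi.sum()
        observed = np.bincount(lab.ravel(), minlength=2) / lab.size
        np.testing.assert_allclose(pi, observed, atol=0.02)

    def test_single_frame_rejected(self):
        with pytest.raises(InsufficientDataError):
            transition_matrix(LabelTrajectory(labels=np.zeros((1, 5), int),
                                              temperature=1))


class TestPopulationsAndDetection:
    def _model2(self):
        return ClusterModel(
            modes=np.zeros((2, 1)), weights=np.array([0.5, 0.5]),
            means=np.zeros((2, 1)), covariances=np.ones((2, 1, 1)),
            labels_map={0: LIQUID, 1: GEL}, bandwidth=np.ones(1))

    def test_all_gel(self):
        trajs = {300.0: LabelTrajectory(labels=np.ones((5, 10), int),
                                        temperature=300.0)}
        curve = population_curve(trajs, self._model2())
        assert curve[300.0][GEL] == pytest.approx(1.0)

    def test_half_half(self):
        lab = np.zeros((2, 10), int)
        lab[:, :5] = 1
        curve = population_curve(
            {1.0: LabelTrajectory(labels=lab, temperature=1.0)},
            self._model2())
        assert curve[1.0][GEL] == pytest.approx(0.5)
        assert curve[1.0][LIQUID] == pytest.approx(0.5)

    def test_detect_bracketing_interval(self):
        assert detect_transition({273: 0.9, 293: 0.8, 323: 0.2,
                                  333: 0.1}) == (293, 323)

    def test_shallow_drift_returns_none(self):
        assert detect_transition({273: 0.55, 293: 0.52, 323: 0.48,
                                  333: 0.45}) is None

    def test_step_at_grid_edge(self):
        assert detect_transition({273: 1.0, 293: 1.0, 323: 1.0,
                                  333: 0.0}) == (323, 333)

    def test_needs_three_temperatures(self):
        with pytest.raises(InsufficientDataError):
            detect_transition({273: 1.0, 333: 0.0})
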