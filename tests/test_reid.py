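"""Clustering core, per-frame uniqueness, mapping, full re-ID pipeline."""

import itertools

import numpy as np
import pytest

from reidpose.errors import CardinalityError, MappingError, ValidationError
from reidpose.evaluation import match_clusters_to_truth
from reidpose.reid import (
    UNKNOWN_LABEL, IdentityAssignment, apply_mapping, assign_frame,
    fit_kmeans, hungarian_min_cost, kmeanspp_init, run_reid,
)
from reidpose.simulate import ScenarioConfig, simulate_session
from reidpose.types import BoundingBox, Detection
from reidpose.validation import brute_force_min_cost, exhaustive_bipartition_sse


def _det(det_id, embedding, frame=0):
    return Detection(det_id, BoundingBox(frame, 0, 0, 10, 10),
                     embedding=np.asarray(embedding, dtype=float))


class TestFitKmeans:
    def test_k1_closed_form(self, rng):
        X = rng.normal(size=(40, 3))
        model = fit_kmeans(X, K=1, seed=0)
        np.testing.assert_allclose(model.centroids[0], X.mean(axis=0), atol=1e-9)
        assert model.inertia == pytest.approx(
            float(((X - X.mean(axis=0)) ** 2).sum()), rel=1e-9)

    def test_two_tight_groups_recovered(self, rng):
        a = rng.normal(scale=0.01, size=(4, 2))
        b = rng.normal(scale=0.01, size=(4, 2)) + 100.0
        X = np.vstack([a, b])
        model = fit_kmeans(X, K=2, seed=0)
        assert model.inertia == pytest.approx(
            exhaustive_bipartition_sse(X), rel=1e-9)
        labels = np.linalg.norm(
            X[:, None] - model.centroids[None], axis=-1).argmin(1)
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]

    def test_duplicate_points_zero_inertia(self):
        p, q = np.array([1.0, 1.0]), np.array([5.0, -2.0])
        model = fit_kmeans(np.array([p, p, q, q]), K=2, seed=0)
        assert model.inertia == pytest.approx(0.0, abs=1e-12)
        got = {tuple(c) for c in np.round(model.centroids, 9)}
        assert got == {tuple(p), tuple(q)}

    def test_too_few_points_rejected(self):
        with pytest.raises(CardinalityError):
            fit_kmeans(np.zeros((2, 3)), K=5)


class TestKmeansppInit:
    def test_k_equals_n_selects_every_point(self, rng):
        pts = rng.normal(size=(6, 2))
        for _ in range(10):
            centroids = kmeanspp_init(pts, 6, rng)
            assert {tuple(c) for c in centroids} == {tuple(p) for p in pts}

    def test_second_centroid_prefers_far_group(self, rng):
        pts = np.vstack([np.zeros((5, 2)) + rng.normal(scale=0.1, size=(5, 2)),
                         np.full((5, 2), 50.0) + rng.normal(scale=0.1, size=(5, 2))])
        opposite = 0
        for _ in range(1000):
            c = kmeanspp_init(pts, 2, rng)
            if abs(c[0, 0] - c[1, 0]) > 25:
                opposite += 1
        assert opposite >= 990

    def test_k1_is_uniform(self, rng):
        pts = np.arange(8, dtype=float).reshape(-1, 1)
        counts = np.zeros(8)
        for _ in range(10_000):
            c = kmeanspp_init(pts, 1, rng)
            counts[int(c[0, 0])] += 1
        np.testing.assert_allclose(counts / 10_000, 1 / 8, atol=0.02)

    def test_k_exceeding_points_rejected(self, rng):
        with pytest.raises(CardinalityError):
            kmeanspp_init(np.zeros((3, 2)), 4, rng)


class TestHungarian:
    def test_diagonal_structure(self):
        C = np.ones((3, 3)) - np.eye(3)
        cols, total = hungarian_min_cost(C)
        assert list(cols) == [0, 1, 2]
        assert total == 0.0

    def test_single_cell(self):
        cols, total = hungarian_min_cost([[3.5]])
        assert list(cols) == [0] and total == 3.5

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(50):
            C = rng.random((4, 4))
            _, total = hungarian_min_cost(C)
            assert total == pytest.approx(brute_force_min_cost(C), abs=1e-12)

    def test_rectangular_uses_cheapest_columns(self, rng):
        C = np.array([[10.0, 1.0, 10.0, 0.5]])
        cols, total = hungarian_min_cost(C)
        assert list(cols) == [3] and total == 0.5

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValidationError):
            hungarian_min_cost(np.zeros((3, 2)))
        with pytest.raises(ValidationError):
            hungarian_min_cost(np.array([[np.inf, 1.0]]))


class TestAssignFrame:
    @pytest.fixture
    def model(self):
        return fit_kmeans(np.array([[0.0, 0.0], [0.0, 0.0],
                                    [10.0, 0.0], [10.0, 0.0]]), K=2, seed=0)

    def test_single_detection_assigned_to_nearest(self, model):
        (a,) = assign_frame([_det(1, [9.0, 0.5])], model)
        assert a.status == "assigned"
        centroid = model.centroids[a.cluster]
        assert np.linalg.norm(centroid - [10, 0]) < 1e-9
        assert a.distance == pytest.approx(np.hypot(1.0, 0.5), rel=1e-9)

    def test_flag_mode_marks_all_colliders_conflicted(self, model):
        dets = [_det(1, [0.1, 0.0]), _det(2, [-0.1, 0.0]), _det(3, [10.0, 0.0])]
        out = assign_frame(dets, model, mode="flag")
        statuses = {a.detection_id: a.status for a in out}
        assert statuses == {1: "conflicted", 2: "conflicted", 3: "assigned"}
        for a in out:
            if a.status == "conflicted":
                assert a.cluster is None and a.distance is None

    def test_optimal_mode_matches_permutation_minimum(self, rng):
        centroids = rng.normal(size=(3, 2)) * 5
        model = fit_kmeans(np.repeat(centroids, 2, axis=0), K=3, seed=0)
        for _ in range(20):
            dets = [_det(i, rng.normal(size=2) * 5) for i in range(3)]
            out = assign_frame(dets, model, mode="optimal")
            cost = sum(a.distance ** 2 for a in out)
            X = np.array([d.embedding for d in dets])
            D2 = ((X[:, None] - model.centroids[None]) ** 2).sum(-1)
            best = min(sum(D2[i, p[i]] for i in range(3))
                       for p in itertools.permutations(range(3)))
            assert cost == pytest.approx(best, rel=1e-9)

    def test_optimal_mode_conflicts_surplus_detections(self, model):
        dets = [_det(i, [0.0, 0.0]) for i in range(4)]
        out = assign_frame(dets, model, mode="optimal")
        assert sum(a.status == "assigned" for a in out) == 2
        assert sum(a.status == "conflicted" for a in out) == 2

    def test_per_frame_uniqueness_invariant(self, small_scenario):
        model = fit_kmeans(
            np.array([d.embedding for d in small_scenario.detections]), K=3, seed=0)
        for mode in ("flag", "optimal"):
            for f in small_scenario.frames:
                out = assign_frame(f.detections, model, mode=mode)
                clusters = [a.cluster for a in out if a.cluster is not None]
                assert len(clusters) == len(set(clusters))

    def test_flag_never_assigns_more_than_optimal(self, small_scenario):
        model = fit_kmeans(
            np.array([d.embedding for d in small_scenario.detections]), K=3, seed=0)
        for f in small_scenario.frames:
            n_flag = sum(a.status == "assigned"
                         for a in assign_frame(f.detections, model, "flag"))
            n_opt = sum(a.status == "assigned"
                        for a in assign_frame(f.detections, model, "optimal"))
            assert n_flag <= n_opt


class TestApplyMapping:
    def _assigned(self, det_id, cluster):
        return IdentityAssignment(det_id, 0, cluster, 1.0, "assigned")

    def test_semantic_labels(self):
        out = apply_mapping([self._assigned(1, 0), self._assigned(2, 1)],
                            {0: "Therapist", 1: "Patient"})
        assert [a.label for a in out] == ["Therapist", "Patient"]

    def test_identity_mapping(self):
        out = apply_mapping([self._assigned(1, 1)], {0: "0", 1: "1"})
        assert out[0].label == "1"

    def test_conflicted_gets_reserved_token(self):
        conflicted = IdentityAssignment(1, 0, None, None, "conflicted")
        out = apply_mapping([conflicted], {0: "A", 1: "B"})
        assert out[0].label == UNKNOWN_LABEL

    def test_invalid_mappings_rejected(self):
        a = [self._assigned(1, 0)]
        with pytest.raises(MappingError):
            apply_mapping(a, {0: "A", 1: "A"})        # non-injective
        with pytest.raises(MappingError):
            apply_mapping(a, {0: "A", 2: "B"})        # gap in domain
        with pytest.raises(MappingError):
            apply_mapping(a, {0: "A", 1: UNKNOWN_LABEL})


class TestRunReid:
    def test_zero_noise_scenario_fully_recovered(self):
        cfg = ScenarioConfig(K=3, n_frames=300, noise_sigma=0.0, seed=11)
        sc = simulate_session(cfg)
        for mode in ("flag", "optimal"):
            assignments, _ = run_reid(sc.frames, 3, mode=mode, seed=0)
            assert all(a.status == "assigned" for a in assignments)
            mapping = match_clusters_to_truth(assignments, sc.truth)
            assert all(mapping[a.cluster] == sc.truth[a.detection_id]
                       for a in assignments)

    def test_k1_session_single_label(self):
        cfg = ScenarioConfig(K=1, n_frames=50, seed=5)
        sc = simulate_session(cfg)
        assignments, _ = run_reid(sc.frames, 1, seed=0)
        assert {a.label for a in assignments} == {"0"}
        assert all(a.status == "assigned" for a in assignments)

    def test_deterministic_given_seed(self, small_scenario):
        a1, _ = run_reid(small_scenario.frames, 3, seed=7)
        a2, _ = run_reid(small_scenario.frames, 3, seed=7)
        assert [(x.detection_id, x.cluster, x.status) for x in a1] == \
               [(x.detection_id, x.cluster, x.status) for x in a2]

    def test_monotone_degradation_with_noise(self):
        from reidpose.validation import separation_accuracy_curve
        curve = separation_accuracy_curve(3, separations=(8.0, 2.0, 1.0),
                                          n_seeds=5, n_frames=150)
        acc = curve["mean_accuracy_pct"]
        assert acc[0] >= acc[1] >= acc[2]
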