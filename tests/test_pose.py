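"""Pose features, classifier behaviour, leave-one-session-out evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reidpose.errors import (
    DegenerateTrainingError, FeatureExtractionError, SchemaVersionError,
    ValidationError,
)
from reidpose.pose import (
    UNSCORED, extract_features, group_kfold_evaluate, predict_pose,
    train_classifier,
)
from reidpose.simulate import PoseRecord, simulate_pose_dataset, simulate_skeleton
from reidpose.types import MIDHIP, NECK, RANKLE, RHIP, RKNEE, Skeleton


def _skeleton(seed=0, label="standing", **kw):
    return simulate_skeleton(label, np.random.default_rng(seed), **kw)


def _transformed(sk, dx=0.0, dy=0.0, scale=1.0):
    kp = sk.keypoints.copy()
    live = ~sk.missing
    kp[live, 0] = kp[live, 0] * scale + dx
    kp[live, 1] = kp[live, 1] * scale + dy
    return Skeleton(sk.detection_id, kp, sk.frame_index)


class TestExtractFeatures:
    def test_translation_invariance_example(self):
        sk = _skeleton(1)
        np.testing.assert_allclose(
            extract_features(sk),
            extract_features(_transformed(sk, dx=37.0, dy=-12.0)),
            atol=1e-9,
        )

    def test_scale_invariance_example(self):
        sk = _skeleton(2, label="sitting")
        np.testing.assert_allclose(
            extract_features(sk), extract_features(_transformed(sk, scale=2.0)),
            atol=1e-9,
        )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           dx=st.floats(-500, 500), dy=st.floats(-500, 500),
           scale=st.floats(0.1, 10.0))
    def test_similarity_invariance_property(self, seed, dx, dy, scale):
        rng = np.random.default_rng(seed)
        label = "sitting" if rng.random() < 0.5 else "standing"
        sk = simulate_skeleton(label, rng, keypoint_noise_sigma=4.0,
                               missing_prob=0.2)
        if not (sk.present(NECK) and sk.present(MIDHIP)):
            return
        np.testing.assert_allclose(
            extract_features(sk),
            extract_features(_transformed(sk, dx=dx, dy=dy, scale=scale)),
            rtol=1e-6, atol=1e-6,
        )

    def test_collinear_leg_gives_180_degree_knee(self):
        sk = _skeleton(3)
        kp = sk.keypoints.copy()
        kp[RHIP, :2] = [0.0, 0.0]
        kp[RKNEE, :2] = [0.0, 50.0]
        kp[RANKLE, :2] = [0.0, 100.0]
        feats = extract_features(Skeleton(0, kp))
        assert feats[50] == pytest.approx(180.0, abs=1e-9)  # right knee slot

    def test_angle_features_bounded(self):
        feats = extract_features(_skeleton(4, label="sitting",
                                           keypoint_noise_sigma=10.0))
        assert np.all(feats[50:55] >= 0.0) and np.all(feats[50:55] <= 180.0)

    def test_missing_anchor_is_error(self):
        sk = _skeleton(5)
        kp = sk.keypoints.copy()
        kp[MIDHIP] = 0.0
        with pytest.raises(FeatureExtractionError):
            extract_features(Skeleton(0, kp))


class TestClassifier:
    def test_separable_training_set_fit_exactly(self):
        records = simulate_pose_dataset(n_sessions=2, frames_per_session=50,
                                        keypoint_noise_sigma=0.0,
                                        missing_prob=0.0, seed=0)
        model = train_classifier(records, seed=0)
        preds = predict_pose(model, [r.skeleton for r in records])
        assert preds == [r.label for r in records]

    def test_duplicated_dataset_same_predictions(self):
        records = simulate_pose_dataset(n_sessions=2, frames_per_session=40,
                                        seed=1)
        probe = [r.skeleton for r in simulate_pose_dataset(
            n_sessions=2, frames_per_session=20, seed=2)]
        m1 = train_classifier(records, seed=0)
        m2 = train_classifier(records + records, seed=0)
        assert predict_pose(m1, probe) == predict_pose(m2, probe)

    def test_fixed_seed_reproducible(self):
        records = simulate_pose_dataset(n_sessions=2, frames_per_session=40,
                                        seed=3)
        probe = [r.skeleton for r in records]
        p1 = predict_pose(train_classifier(records, seed=9), probe)
        p2 = predict_pose(train_classifier(records, seed=9), probe)
        assert p1 == p2

    def test_single_class_rejected(self):
        records = [PoseRecord("s", 0, t, _skeleton(t, "sitting"), "sitting")
                   for t in range(10)]
        with pytest.raises(DegenerateTrainingError):
            train_classifier(records)

    def test_missing_anchor_skeleton_unscored(self):
        records = simulate_pose_dataset(n_sessions=2, frames_per_session=40,
                                        seed=4)
        model = train_classifier(records, seed=0)
        broken = _skeleton(1)
        kp = broken.keypoints.copy()
        kp[MIDHIP] = 0.0
        out = predict_pose(model, [records[0].skeleton, Skeleton(0, kp)])
        assert out[0] in ("sitting", "standing")
        assert out[1] == UNSCORED

    def test_batch_order_and_length(self):
        records = simulate_pose_dataset(n_sessions=2, frames_per_session=30,
                                        seed=5)
        model = train_classifier(records, seed=0)
        sks = [r.skeleton for r in records[:17]]
        assert len(predict_pose(model, sks)) == 17

    def test_schema_mismatch_rejected(self):
        records = simulate_pose_dataset(n_sessions=2, frames_per_session=30,
                                        seed=6)
        model = train_classifier(records, seed=0)
        model.schema_version = 99
        with pytest.raises(SchemaVersionError):
            predict_pose(model, [records[0].skeleton])


class TestGroupKFold:
    def test_fold_partition_invariants(self):
        records = simulate_pose_dataset(n_sessions=5, frames_per_session=60,
                                        seed=0)
        reports, _ = group_kfold_evaluate(records, seed=0)
        held_out = [r.session_id for r in reports]
        assert sorted(held_out) == sorted({r.session_id for r in records})
        assert len(held_out) == len(set(held_out)) == 5

    def test_f1_is_harmonic_mean(self):
        records = simulate_pose_dataset(n_sessions=4, frames_per_session=80,
                                        keypoint_noise_sigma=15.0,
                                        missing_prob=0.2, seed=1)
        reports, _ = group_kfold_evaluate(records, seed=0)
        for rep in reports:
            for cls, m in rep.metrics.items():
                if m is None:
                    continue
                p, r, f1 = m
                if p + r > 0:
                    assert f1 == pytest.approx(2 * p * r / (p + r), abs=1e-12)

    def test_separable_dataset_perfect_f1_every_fold(self):
        records = simulate_pose_dataset(n_sessions=4, frames_per_session=60,
                                        keypoint_noise_sigma=0.0,
                                        missing_prob=0.0, seed=2)
        reports, summary = group_kfold_evaluate(records, seed=0)
        for rep in reports:
            for m in rep.metrics.values():
                assert m is not None and m[2] == pytest.approx(1.0)
        assert summary["sitting"]["f1_mean"] == pytest.approx(1.0)

    def test_shuffled_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(0)
        accs = []
        for s in range(10):
            records = simulate_pose_dataset(n_sessions=4,
                                            frames_per_session=120, seed=s)
            labels = [r.label for r in records]
            rng.shuffle(labels)
            shuffled = [PoseRecord(r.session_id, r.identity, r.frame_index,
                                   r.skeleton, l)
                        for r, l in zip(records, labels)]
            reports, _ = group_kfold_evaluate(shuffled, seed=s)
            # frame-weighted recall of sitting ~ chance on balanced labels
            correct = total = 0
            for rep in reports:
                for cls, m in rep.metrics.items():
                    if m is not None:
                        correct += m[1] * rep.n_frames
                        total += rep.n_frames
            accs.append(correct / total)
        assert np.mean(accs) == pytest.approx(0.5, abs=0.05)

    def test_single_session_rejected(self):
        records = simulate_pose_dataset(n_sessions=2, frames_per_session=20,
                                        seed=3)
        only_one = [r for r in records if r.session_id == "session00"]
        with pytest.raises(ValidationError):
            group_kfold_evaluate(only_one)
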