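"""Sitting/standing classification from 25-keypoint skeletons.

Features are translation- and scale-invariant: all keypoints are centred on
MidHip and divided by the torso (Neck-MidHip) length, five joint angles are
appended (left/right knee, left/right hip, trunk inclination from vertical,
all in degrees), plus 25 missingness indicator bits. Missing keypoints
contribute zero coordinates (indicator 1); angles whose inputs are missing
are reported as 0.

The classifier is a gradient-boosted decision-tree ensemble (XGBoost) with
default hyperparameters — no tuning. Evaluation is leave-one-session-out
group-k-fold: every fold trains on all sessions but one and tests on the
held-out session, so no session ever contributes to both sides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import precision_recall_fscore_support
from xgboost import XGBClassifier

from .errors import (
    DegenerateTrainingError,
    FeatureExtractionError,
    SchemaVersionError,
    ValidationError,
)
from .simulate import PoseRecord
from .types import (
    LANKLE, LHIP, LKNEE, MIDHIP, NECK, N_KEYPOINTS,
    RANKLE, RHIP, RKNEE, Skeleton,
)

FEATURE_SCHEMA_VERSION = 1
CLASS_ORDER = ("sitting", "standing")
UNSCORED = "UNSCORED"

#: length of the feature vector: 25 normalized (x, y) pairs + 5 angles + 25 bits
N_FEATURES = 2 * N_KEYPOINTS + 5 + N_KEYPOINTS


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Interior angle at b formed by segments b->a and b->c, in [0, 180]."""
    u, v = a - b, c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    cosv = float(np.dot(u, v) / (nu * nv))
    return math.degrees(math.acos(min(1.0, max(-1.0, cosv))))


def extract_features(skeleton: Skeleton) -> np.ndarray:
    """Translation/scale-invariant feature vector for one skeleton.

    Requires Neck and MidHip (the normalization anchors); raises
    :class:`FeatureExtractionError` when either is missing or coincident.
    """
    kp = skeleton.keypoints
    if not (skeleton.present(NECK) and skeleton.present(MIDHIP)):
        raise FeatureExtractionError(
            f"detection {skeleton.detection_id}: Neck or MidHip missing"
        )
    midhip = kp[MIDHIP, :2]
    neck = kp[NECK, :2]
    torso = float(np.linalg.norm(neck - midhip))
    if torso <= 0:
        raise FeatureExtractionError(
            f"detection {skeleton.detection_id}: zero torso length"
        )
    missing = skeleton.missing
    coords = (kp[:, :2] - midhip) / torso
    coords = np.where(missing[:, None], 0.0, coords)

    def pt(i: int) -> np.ndarray | None:
        return None if missing[i] else kp[i, :2]

    def joint_angle(i: int, j: int, k: int) -> float:
        a, b, c = pt(i), pt(j), pt(k)
        if a is None or b is None or c is None:
            return 0.0
        return _angle_deg(a, b, c)

    knee_r = joint_angle(RHIP, RKNEE, RANKLE)
    knee_l = joint_angle(LHIP, LKNEE, LANKLE)
    hip_r = joint_angle(NECK, RHIP, RKNEE)
    hip_l = joint_angle(NECK, LHIP, LKNEE)
    trunk = _angle_deg(neck, midhip, midhip + np.array([0.0, -1.0]))

    return np.concatenate([
        coords.ravel(),
        [knee_r, knee_l, hip_r, hip_l, trunk],
        missing.astype(float),
    ])


@dataclass
class PoseModel:
    """Trained sit/stand classifier plus its feature schema."""

    classifier: XGBClassifier
    classes: tuple[str, str] = CLASS_ORDER
    schema_version: int = FEATURE_SCHEMA_VERSION
    n_skipped: int = 0


@dataclass
class FoldReport:
    """Held-out metrics of one leave-one-session-out fold.

    ``metrics[class]`` is a (precision, recall, f1) triple, or None when the
    class is absent from the held-out session (undefined metrics).
    """

    session_id: str
    metrics: dict[str, tuple[float, float, float] | None]
    n_frames: int


def _build_matrix(records: list[PoseRecord]) -> tuple[np.ndarray, np.ndarray, int]:
    X, y, skipped = [], [], 0
    for r in records:
        try:
            X.append(extract_features(r.skeleton))
        except FeatureExtractionError:
            skipped += 1
            continue
        y.append(CLASS_ORDER.index(r.label))
    return np.asarray(X), np.asarray(y), skipped


def train_classifier(records: list[PoseRecord], seed: int = 0) -> PoseModel:
    """Fit the gradient-boosted classifier; deterministic given ``seed``."""
    X, y, skipped = _build_matrix(records)
    if len(X) == 0 or len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise DegenerateTrainingError(
            "training requires at least two examples of each class"
        )
    clf = XGBClassifier(random_state=seed, n_jobs=1)
    clf.fit(X, y)
    return PoseModel(classifier=clf, n_skipped=skipped)


def predict_pose(model: PoseModel, skeletons: list[Skeleton]) -> list[str]:
    """One label per skeleton, in order; anchorless skeletons -> "UNSCORED"."""
    if model.schema_version != FEATURE_SCHEMA_VERSION:
        raise SchemaVersionError(
            f"model schema v{model.schema_version}, library expects "
            f"v{FEATURE_SCHEMA_VERSION}"
        )
    feats, where = [], []
    labels = [UNSCORED] * len(skeletons)
    for i, sk in enumerate(skeletons):
        try:
            feats.append(extract_features(sk))
            where.append(i)
        except FeatureExtractionError:
            continue
    if feats:
        pred = model.classifier.predict(np.asarray(feats))
        for i, p in zip(where, pred):
            labels[i] = model.classes[int(p)]
    return labels


def group_kfold_evaluate(records: list[PoseRecord], seed: int = 0,
                         ) -> tuple[list[FoldReport], dict]:
    """Leave-one-session-out cross-validation.

    One fold per session; metrics per class on the held-out session, plus a
    summary in which each class's precision/recall/F1 mean and std across
    folds are weighted by the number of held-out frames (sessions with the
    class absent are excluded from that class's summary).
    """
    sessions = sorted({r.session_id for r in records})
    if len(sessions) < 2:
        raise ValidationError("need at least two distinct sessions")
    reports: list[FoldReport] = []
    for held_out in sessions:
        train = [r for r in records if r.session_id != held_out]
        test = [r for r in records if r.session_id == held_out]
        model = train_classifier(train, seed=seed)
        preds = predict_pose(model, [r.skeleton for r in test])
        pairs = [(r.label, p) for r, p in zip(test, preds) if p != UNSCORED]
        y_true = [t for t, _ in pairs]
        y_pred = [p for _, p in pairs]
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=list(CLASS_ORDER), zero_division=0.0
        )
        metrics: dict[str, tuple[float, float, float] | None] = {}
        for i, cls in enumerate(CLASS_ORDER):
            if cls not in y_true:
                metrics[cls] = None  # undefined for this fold
            else:
                metrics[cls] = (float(prec[i]), float(rec[i]), float(f1[i]))
        reports.append(FoldReport(held_out, metrics, n_frames=len(pairs)))

    summary: dict = {}
    for cls in CLASS_ORDER:
        vals = np.array([r.metrics[cls] for r in reports if r.metrics[cls] is not None])
        wts = np.array([r.n_frames for r in reports if r.metrics[cls] is not None],
                       dtype=float)
        entry = {}
        for j, name in enumerate(("precision", "recall", "f1")):
            mean = float(np.average(vals[:, j], weights=wts))
            std = float(np.sqrt(np.average((vals[:, j] - mean) ** 2, weights=wts)))
            entry[f"{name}_mean"] = mean
            entry[f"{name}_std"] = std
        summary[cls] = entry
    return reports, summary
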