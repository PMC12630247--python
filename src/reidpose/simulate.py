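"""Synthetic multi-person session generator.

Emulates the recording setting the pipeline targets: K individuals with
distinct appearance signatures move freely in a room, occasionally leaving
the camera's field of view (or being occluded) and re-entering later.

* Appearance: each identity owns a centroid in embedding space; every
  detection's embedding is that centroid plus isotropic Gaussian noise.
  The separation-to-noise ratio is the single difficulty knob.
* Presence: an independent two-state Markov chain per identity
  (absent -> present with probability ``enter_prob``, present -> absent with
  ``exit_prob``), started in the present state. Mean visible bout length is
  1/exit_prob frames and mean absence 1/enter_prob frames; the long-run
  present fraction is a/(a+b).
* Motion: each box centre follows a reflected Gaussian random walk inside
  the image bounds — plausible for trajectory plots, not biomechanical.
* Pose: ``simulate_skeleton`` builds geometrically distinct sitting and
  standing 25-keypoint stick figures with per-keypoint pixel noise and
  independent keypoint dropout, used for the sit/stand classifier tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigurationError, ValidationError
from .types import (
    LANKLE, LBIGTOE, LEAR, LELBOW, LEYE, LHEEL, LHIP, LKNEE, LSHOULDER,
    LSMALLTOE, LWRIST, MIDHIP, NECK, NOSE, N_KEYPOINTS,
    RANKLE, RBIGTOE, REAR, RELBOW, REYE, RHEEL, RHIP, RKNEE, RSHOULDER,
    RSMALLTOE, RWRIST,
    BoundingBox, Detection, FrameRecord, Skeleton,
)


@dataclass
class ScenarioConfig:
    """Generative parameters of one synthetic session.

    Defaults describe a moderately easy session: well-separated appearance
    centroids (separation 10 in embedding units against unit noise), the
    presence chain (a=0.2, b=0.05, long-run present fraction 0.8), and a
    720p image with gentle box motion.
    """

    K: int = 2
    n_frames: int = 2000
    embedding_dim: int = 64
    centroid_separation: float = 10.0
    noise_sigma: float = 1.0
    enter_prob: float = 0.2
    exit_prob: float = 0.05
    confusable_pair: tuple[int, int, float] | None = None
    image_size: tuple[int, int] = (1280, 720)
    motion_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.K <= 8:
            raise ValidationError(f"K must be in 1..8, got {self.K}")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if not (0 < self.enter_prob < 1 and 0 < self.exit_prob < 1):
            raise ValidationError("enter_prob and exit_prob must lie in (0, 1)")
        if self.confusable_pair is not None:
            i, j, reduced = self.confusable_pair
            if i == j or not (0 <= i < self.K and 0 <= j < self.K):
                raise ValidationError("confusable_pair indices must be distinct identities")
            if not reduced < self.centroid_separation:
                raise ValidationError(
                    "reduced_separation must be smaller than centroid_separation"
                )


@dataclass
class SessionScenario:
    """A generated session together with its ground truth."""

    config: ScenarioConfig
    frames: list[FrameRecord]
    truth: dict[int, int]              # detection_id -> identity in {0..K-1}
    centroids: np.ndarray              # (K, d)
    presence: np.ndarray               # (K, n_frames) bool

    @property
    def detections(self) -> list[Detection]:
        return [d for f in self.frames for d in f.detections]


@dataclass
class PoseRecord:
    """One labelled skeleton frame for classifier training/evaluation."""

    session_id: str
    identity: int
    frame_index: int
    skeleton: Skeleton
    label: str

    def __post_init__(self):
        if self.label not in ("sitting", "standing"):
            raise ValidationError(f"label must be sitting/standing, got {self.label}")


# ---------------------------------------------------------------------------
# session simulation
# ---------------------------------------------------------------------------

def _draw_centroids(cfg: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Gaussian centroids rescaled so the minimum pairwise distance equals
    centroid_separation; a confusable pair is then pulled to exactly its
    reduced separation."""
    c = rng.standard_normal((cfg.K, cfg.embedding_dim))
    if cfg.K == 1:
        return c
    d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    dmin = d.min()
    if dmin == 0:
        raise ConfigurationError("degenerate centroid draw (coincident points)")
    c *= cfg.centroid_separation / dmin
    if cfg.confusable_pair is not None:
        i, j, reduced = cfg.confusable_pair
        direction = c[j] - c[i]
        c[j] = c[i] + direction * (reduced / np.linalg.norm(direction))
    return c


def simulate_session(config: ScenarioConfig) -> SessionScenario:
    """Generate one session; reproducible given ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    W, H = cfg.image_size

    # per-identity box geometry
    widths = rng.uniform(60, 100, size=cfg.K)
    heights = rng.uniform(140, 220, size=cfg.K)
    if cfg.K * float(np.min(widths * heights)) > W * H:
        raise ConfigurationError(
            f"{cfg.K} boxes of minimum area {np.min(widths * heights):.0f} px^2 "
            f"cannot fit a {W}x{H} image"
        )

    centroids = _draw_centroids(cfg, rng)

    # presence chains, initial state present
    presence = np.zeros((cfg.K, cfg.n_frames), dtype=bool)
    presence[:, 0] = True
    u = rng.random((cfg.K, cfg.n_frames))
    for t in range(1, cfg.n_frames):
        prev = presence[:, t - 1]
        presence[:, t] = np.where(prev, u[:, t] >= cfg.exit_prob, u[:, t] < cfg.enter_prob)

    # reflected random walks of box centres
    cx = np.empty((cfg.K, cfg.n_frames))
    cy = np.empty((cfg.K, cfg.n_frames))
    lo_x, hi_x = widths / 2, W - widths / 2
    lo_y, hi_y = heights / 2, H - heights / 2
    cx[:, 0] = rng.uniform(lo_x, hi_x)
    cy[:, 0] = rng.uniform(lo_y, hi_y)
    steps_x = rng.normal(0, cfg.motion_sigma, size=(cfg.K, cfg.n_frames))
    steps_y = rng.normal(0, cfg.motion_sigma, size=(cfg.K, cfg.n_frames))
    for t in range(1, cfg.n_frames):
        cx[:, t] = _reflect(cx[:, t - 1] + steps_x[:, t], lo_x, hi_x)
        cy[:, t] = _reflect(cy[:, t - 1] + steps_y[:, t], lo_y, hi_y)

    frames: list[FrameRecord] = []
    truth: dict[int, int] = {}
    next_id = 0
    for t in range(cfg.n_frames):
        dets: list[Detection] = []
        for k in range(cfg.K):
            if not presence[k, t]:
                continue
            emb = centroids[k].copy()
            if cfg.noise_sigma > 0:
                emb = emb + rng.normal(0, cfg.noise_sigma, size=cfg.embedding_dim)
            box = BoundingBox(
                frame_index=t,
                x_min=float(cx[k, t] - widths[k] / 2),
                y_min=float(cy[k, t] - heights[k] / 2),
                width=float(widths[k]),
                height=float(heights[k]),
                confidence=1.0,
            )
            dets.append(Detection(next_id, box, embedding=emb))
            truth[next_id] = k
            next_id += 1
        frames.append(FrameRecord(t, dets))

    return SessionScenario(cfg, frames, truth, centroids, presence)


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    x = np.where(x < lo, 2 * lo - x, x)
    x = np.where(x > hi, 2 * hi - x, x)
    return np.clip(x, lo, hi)  # guard against double overshoot


# ---------------------------------------------------------------------------
# skeleton simulation
# ---------------------------------------------------------------------------

def simulate_skeleton(label: str, rng: np.random.Generator,
                      keypoint_noise_sigma: float = 0.0,
                      missing_prob: float = 0.0,
                      scale: float = 100.0,
                      anchor: tuple[float, float] = (0.0, 0.0),
                      detection_id: int = 0,
                      frame_index: int | None = None) -> Skeleton:
    """Build a sitting or standing 25-keypoint stick figure.

    ``scale`` is the torso (Neck-MidHip) length in pixels; limb lengths are
    proportional to it. Standing figures draw a hip-knee-ankle angle in
    [165, 180] degrees (hip-to-ankle vertical extent about twice the torso),
    sitting figures draw it in [80, 100] (extent about one torso: thighs
    horizontal). Gaussian pixel noise is added per keypoint, then each
    keypoint is dropped independently with ``missing_prob``.
    """
    if label not in ("sitting", "standing"):
        raise ValidationError(f"label must be sitting/standing, got {label}")
    if not 0.0 <= missing_prob <= 1.0:
        raise ValidationError(f"missing_prob must be in [0,1], got {missing_prob}")
    if scale <= 0:
        raise ValidationError("scale must be positive")

    T = scale
    ax, ay = anchor
    kp = np.zeros((N_KEYPOINTS, 3))

    midhip = np.array([ax, ay])
    neck = midhip + np.array([0.0, -T])          # y-down: up is negative
    nose = neck + np.array([0.0, -0.35 * T])
    kp[MIDHIP, :2], kp[NECK, :2], kp[NOSE, :2] = midhip, neck, nose
    kp[REYE, :2] = nose + np.array([-0.06 * T, -0.05 * T])
    kp[LEYE, :2] = nose + np.array([0.06 * T, -0.05 * T])
    kp[REAR, :2] = nose + np.array([-0.12 * T, 0.0])
    kp[LEAR, :2] = nose + np.array([0.12 * T, 0.0])
    kp[RSHOULDER, :2] = neck + np.array([-0.25 * T, 0.05 * T])
    kp[LSHOULDER, :2] = neck + np.array([0.25 * T, 0.05 * T])
    kp[RELBOW, :2] = kp[RSHOULDER, :2] + np.array([-0.1 * T, 0.45 * T])
    kp[LELBOW, :2] = kp[LSHOULDER, :2] + np.array([0.1 * T, 0.45 * T])
    kp[RWRIST, :2] = kp[RELBOW, :2] + np.array([0.0, 0.45 * T])
    kp[LWRIST, :2] = kp[LELBOW, :2] + np.array([0.0, 0.45 * T])
    kp[RHIP, :2] = midhip + np.array([-0.12 * T, 0.0])
    kp[LHIP, :2] = midhip + np.array([0.12 * T, 0.0])

    knee_angle = (rng.uniform(165.0, 180.0) if label == "standing"
                  else rng.uniform(80.0, 100.0))
    # thigh direction measured from vertical (y-down)
    thigh_from_vertical = 0.0 if label == "standing" else 90.0
    for hip, knee, ankle, side in (
        (RHIP, RKNEE, RANKLE, -1.0),
        (LHIP, LKNEE, LANKLE, 1.0),
    ):
        a = math.radians(thigh_from_vertical)
        thigh = np.array([side * math.sin(a), math.cos(a)]) * T
        kp[knee, :2] = kp[hip, :2] + thigh
        # interior knee angle between (hip - knee) and (ankle - knee)
        dev = math.radians(180.0 - knee_angle)
        up = kp[hip, :2] - kp[knee, :2]
        shank = -_rotate(up, side * dev)
        kp[ankle, :2] = kp[knee, :2] + shank

    kp[RHEEL, :2] = kp[RANKLE, :2] + np.array([-0.05 * T, 0.05 * T])
    kp[LHEEL, :2] = kp[LANKLE, :2] + np.array([0.05 * T, 0.05 * T])
    kp[RBIGTOE, :2] = kp[RANKLE, :2] + np.array([-0.15 * T, 0.08 * T])
    kp[LBIGTOE, :2] = kp[LANKLE, :2] + np.array([0.15 * T, 0.08 * T])
    kp[RSMALLTOE, :2] = kp[RBIGTOE, :2] + np.array([-0.04 * T, 0.0])
    kp[LSMALLTOE, :2] = kp[LBIGTOE, :2] + np.array([0.04 * T, 0.0])

    if keypoint_noise_sigma > 0:
        kp[:, :2] += rng.normal(0, keypoint_noise_sigma, size=(N_KEYPOINTS, 2))
    kp[:, 2] = rng.uniform(0.5, 1.0, size=N_KEYPOINTS)
    dropped = rng.random(N_KEYPOINTS) < missing_prob
    kp[dropped] = 0.0
    return Skeleton(detection_id, kp, frame_index=frame_index)


def _rotate(v: np.ndarray, angle_rad: float) -> np.ndarray:
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def knee_angle(skeleton: Skeleton, side: str = "right") -> float | None:
    """Interior hip-knee-ankle angle in degrees, None if a point is missing."""
    hip, knee, ankle = (RHIP, RKNEE, RANKLE) if side == "right" else (LHIP, LKNEE, LANKLE)
    if not (skeleton.present(hip) and skeleton.present(knee) and skeleton.present(ankle)):
        return None
    a = skeleton.keypoints[hip, :2] - skeleton.keypoints[knee, :2]
    b = skeleton.keypoints[ankle, :2] - skeleton.keypoints[knee, :2]
    cosv = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return math.degrees(math.acos(np.clip(cosv, -1.0, 1.0)))


# ---------------------------------------------------------------------------
# labelled pose corpus
# ---------------------------------------------------------------------------

def simulate_pose_dataset(n_sessions: int = 10,
                          frames_per_session: int = 500,
                          class_balance: float = 0.5,
                          keypoint_noise_sigma: float = 6.0,
                          missing_prob: float = 0.1,
                          scale: float = 100.0,
                          seed: int = 0) -> list[PoseRecord]:
    """Generate a labelled multi-session sit/stand corpus.

    Per-session sitting proportions are drawn from a Beta distribution with
    mean ``class_balance`` (concentration 100), mimicking session-to-session
    composition differences; records are grouped by session_id so that
    leave-one-session-out evaluation is meaningful.
    """
    if n_sessions < 2:
        raise ValidationError("n_sessions must be >= 2")
    if not 0.0 < class_balance < 1.0:
        raise ValidationError(f"class_balance must be in (0,1), got {class_balance}")
    rng = np.random.default_rng(seed)
    kappa = 100.0
    records: list[PoseRecord] = []
    for s in range(n_sessions):
        session_id = f"session{s:02d}"
        p_sit = rng.beta(class_balance * kappa, (1 - class_balance) * kappa)
        anchor = (rng.uniform(200, 1000), rng.uniform(200, 500))
        for t in range(frames_per_session):
            label = "sitting" if rng.random() < p_sit else "standing"
            sk = simulate_skeleton(
                label, rng,
                keypoint_noise_sigma=keypoint_noise_sigma,
                missing_prob=missing_prob,
                scale=scale,
                anchor=anchor,
                detection_id=len(records),
                frame_index=t,
            )
            records.append(PoseRecord(session_id, 0, t, sk, label))
    return records


def attach_skeletons(scenario: SessionScenario, seed: int = 0,
                     switch_prob: float = 0.01,
                     keypoint_noise_sigma: float = 2.0,
                     missing_prob: float = 0.05,
                     ) -> tuple[dict[int, Skeleton], dict[int, str]]:
    """Give every detection of a scenario a skeleton and a pose label.

    Each identity carries a persistent sit/stand state that flips with
    ``switch_prob`` per frame, so pose runs are realistically bursty.
    Returns (detection_id -> Skeleton, detection_id -> label).
    """
    rng = np.random.default_rng(seed)
    state = {k: ("sitting" if rng.random() < 0.5 else "standing")
             for k in range(scenario.config.K)}
    skeletons: dict[int, Skeleton] = {}
    labels: dict[int, str] = {}
    for frame in scenario.frames:
        for k in state:
            if rng.random() < switch_prob:
                state[k] = "standing" if state[k] == "sitting" else "sitting"
        for det in frame.detections:
            k = scenario.truth[det.detection_id]
            label = state[k]
            sk = simulate_skeleton(
                label, rng,
                keypoint_noise_sigma=keypoint_noise_sigma,
                missing_prob=missing_prob,
                scale=det.box.height / 3.0,
                anchor=(det.box.cx, det.box.cy),
                detection_id=det.detection_id,
                frame_index=frame.frame_index,
            )
            skeletons[det.detection_id] = sk
            labels[det.detection_id] = label
    return skeletons, labels


def config_to_dict(cfg: ScenarioConfig) -> dict:
    d = asdict(cfg)
    d["image_size"] = list(cfg.image_size)
    if cfg.confusable_pair is not None:
        d["confusable_pair"] = list(cfg.confusable_pair)
    return d
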