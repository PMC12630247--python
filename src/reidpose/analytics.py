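"""Downstream behavioural measures.

* Centroid trajectories: per-identity time series of bounding-box centres,
  with gaps where the identity is absent (never interpolated).
* Pose event intervals: maximal constant-label runs of the per-frame
  sit/stand sequence, with optional minimum-duration smoothing.
* Session joint variance: var(X) + var(Y) (sample variance, n-1) of one
  keypoint — by default the neck — over qualifying frames of a session.
  Restricting to sitting frames turns neck variance into an index of head
  movement while seated, uncontaminated by postural changes.
* Cross-session trend: ordinary least squares of the per-session variance
  on the session ordinal, with a two-sided t-test on the slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .reid import UNKNOWN_LABEL, IdentityAssignment
from .types import NECK, BoundingBox, Skeleton


@dataclass
class TrackSeries:
    """Ordered (frame, cx, cy) centroid samples for one labelled identity."""

    label: str
    frames: np.ndarray
    cx: np.ndarray
    cy: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.frames)
        if f.size > 1 and not np.all(np.diff(f) > 0):
            raise ValidationError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class PoseEventInterval:
    label: str
    start_frame: int
    end_frame: int  # inclusive
    duration: int   # number of scored frames in the run

    def __post_init__(self):
        if self.start_frame > self.end_frame:
            raise ValidationError("interval start must be <= end")


@dataclass
class SessionVarianceRecord:
    session_index: int
    identity: str
    joint: int
    variance_total: float   # pixel^2, var(X) + var(Y)
    n_frames_used: int
    n_excluded: int = 0

    def __post_init__(self):
        if self.variance_total < 0:
            raise ValidationError("variance must be >= 0")
        if self.n_frames_used < 2:
            raise ValidationError("variance needs at least 2 frames")


@dataclass
class TrendResult:
    slope: float            # pixel^2 per session
    intercept: float
    p_value: float
    n_sessions: int
    method: str = "ols_t"
    degenerate: bool = False  # zero-residual perfect fit


# ---------------------------------------------------------------------------

def centroid_tracks(assignments: list[IdentityAssignment],
                    boxes: dict[int, BoundingBox]) -> dict[str, TrackSeries]:
    """One centroid series per semantic label; UNKNOWN detections excluded."""
    series: dict[str, list[tuple[int, float, float]]] = {}
    for a in assignments:
        if a.label is None or a.label == UNKNOWN_LABEL:
            continue
        box = boxes[a.detection_id]
        series.setdefault(a.label, []).append((a.frame_index, box.cx, box.cy))
    out = {}
    for label, rows in series.items():
        rows.sort(key=lambda r: r[0])
        arr = np.asarray(rows, dtype=float)
        out[label] = TrackSeries(label, arr[:, 0].astype(int), arr[:, 1], arr[:, 2])
    return out


def pose_event_intervals(per_frame_labels: list[tuple[int, str]],
                         min_duration: int = 1) -> list[PoseEventInterval]:
    """Run-length-encode an ordered per-frame label sequence.

    UNSCORED frames break runs and are not counted. Runs shorter than
    ``min_duration`` are merged into the neighbouring longer run (preferring
    the preceding run on ties); an isolated short run with no neighbour is
    kept as is.
    """
    runs: list[list] = []  # [label, start, end, frames-in-run]
    for frame, label in per_frame_labels:
        if label == "UNSCORED":
            runs.append(None)  # run breaker
            continue
        if runs and runs[-1] is not None and runs[-1][0] == label:
            runs[-1][2] = frame
            runs[-1][3] += 1
        else:
            runs.append([label, frame, frame, 1])
    # smoothing operates within each unbroken segment
    intervals: list[PoseEventInterval] = []
    segment: list[list] = []
    for r in runs + [None]:
        if r is not None:
            segment.append(r)
            continue
        intervals.extend(_smooth_segment(segment, min_duration))
        segment = []
    return intervals


def _smooth_segment(runs: list[list], min_duration: int) -> list[PoseEventInterval]:
    runs = [list(r) for r in runs]
    while len(runs) > 1:
        short = [i for i, r in enumerate(runs) if r[3] < min_duration]
        if not short:
            break
        i = min(short, key=lambda i: runs[i][3])
        prev = runs[i - 1] if i > 0 else None
        nxt = runs[i + 1] if i < len(runs) - 1 else None
        if nxt is None or (prev is not None and prev[3] >= nxt[3]):
            target = prev
        else:
            target = nxt
        runs[i][0] = target[0]  # relabel, then coalesce adjacent equal labels
        merged: list[list] = []
        for r in runs:
            if merged and merged[-1][0] == r[0]:
                merged[-1][2] = r[2]
                merged[-1][3] += r[3]
            else:
                merged.append(r)
        runs = merged
    return [PoseEventInterval(label, start, end, n) for label, start, end, n in runs]


def joint_variance_from_xy(x: np.ndarray, y: np.ndarray) -> float:
    """var(X) + var(Y) with the n-1 (sample) denominator."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(
            f"variance needs at least 2 frames, got {x.size}"
        )
    return float(np.var(x, ddof=1) + np.var(y, ddof=1))


def session_joint_variance(skeletons: list[Skeleton], joint: int = NECK,
                           frame_filter: set[int] | None = None,
                           session_index: int = 0,
                           identity: str = "") -> SessionVarianceRecord:
    """Total positional variance of one keypoint over qualifying frames.

    Qualifying frames are those where the joint is present (confidence > 0)
    and, when ``frame_filter`` is given (for example the set of sitting
    frames), the skeleton's frame is in the filter. Excluded frames are
    counted in ``n_excluded``.
    """
    xs, ys, excluded = [], [], 0
    for sk in skeletons:
        if frame_filter is not None and sk.frame_index not in frame_filter:
            excluded += 1
            continue
        if not sk.present(joint):
            excluded += 1
            continue
        xs.append(sk.keypoints[joint, 0])
        ys.append(sk.keypoints[joint, 1])
    if len(xs) < 2:
        raise InsufficientDataError(
            f"only {len(xs)} qualifying frames for joint {joint}"
        )
    return SessionVarianceRecord(
        session_index=session_index,
        identity=identity,
        joint=joint,
        variance_total=joint_variance_from_xy(np.array(xs), np.array(ys)),
        n_frames_used=len(xs),
        n_excluded=excluded,
    )


def variance_trend(records: list[SessionVarianceRecord]) -> TrendResult:
    """OLS of variance on session ordinal with a two-sided t-test on the slope.

    A zero-residual perfect fit reports p_value = 0 with the degeneracy flag
    set (the t statistic is unbounded there).
    """
    if len(records) < 3:
        raise InsufficientDataError(
            f"trend needs at least 3 sessions, got {len(records)}"
        )
    xs = np.array([r.session_index for r in records], dtype=float)
    ys = np.array([r.variance_total for r in records], dtype=float)
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = ys - (slope * xs + intercept)
    ss_res = float(np.sum(resid ** 2))
    if ss_res <= 1e-12 * max(1.0, float(np.sum(ys ** 2))):
        return TrendResult(float(slope), float(intercept), 0.0, len(records),
                           degenerate=True)
    res = stats.linregress(xs, ys)
    return TrendResult(float(res.slope), float(res.intercept),
                       float(res.pvalue), len(records))
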