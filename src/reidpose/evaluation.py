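"""Scoring of re-identification output against ground truth, plus track audits.

Accuracy follows the excluding-empty-frames convention: frames with zero
detections are counted but excluded from the denominator. A frame counts as
correct only when every detection in it is labelled correctly; conflicted
(UNKNOWN) predictions are incorrect. Detection-level accuracy is also
emitted for transparency, and a per-identity confusion matrix is counted at
detection granularity.

``audit_tracks`` measures identity over-detection of an external tracker's
MOT file: the signed difference between the number of distinct track ids it
emitted and the true number of individuals.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import CoverageError, SamplingError
from .reid import UNKNOWN_LABEL, IdentityAssignment
from .types import BoundingBox, FrameRecord


@dataclass
class VideoScore:
    video_id: str
    N: int
    cases: int
    cases_excl_empty: int
    n_correct: int
    n_incorrect: int
    detection_accuracy: float | None = None

    @property
    def accuracy(self) -> float | None:
        """Frame accuracy in percent, None when no frame was scored."""
        denom = self.n_correct + self.n_incorrect
        return None if denom == 0 else 100.0 * self.n_correct / denom


@dataclass
class ConfusionMatrix:
    """Detection-level confusion counts as a true-by-predicted DataFrame."""

    counts: pd.DataFrame

    @property
    def total(self) -> int:
        return int(self.counts.values.sum())

    @property
    def row_marginals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def detection_accuracy(self) -> float | None:
        common = [l for l in self.counts.index if l in self.counts.columns]
        diag = sum(int(self.counts.loc[l, l]) for l in common)
        return None if self.total == 0 else 100.0 * diag / self.total


@dataclass
class TrackAudit:
    ground_truth_N: int
    detected_unique_ids: int

    @property
    def difference(self) -> int:
        """Signed over-detection (negative = under-detection)."""
        return self.detected_unique_ids - self.ground_truth_N


# ---------------------------------------------------------------------------

def score_video(predicted_labels: dict[int, str], truth_labels: dict[int, str],
                frames: list[FrameRecord], video_id: str = "",
                N: int | None = None) -> tuple[VideoScore, ConfusionMatrix]:
    """Score predictions (keyed by detection_id) against ground truth."""
    if N is None:
        N = len(set(truth_labels.values()))
    cases = len(frames)
    n_correct = n_incorrect = 0
    det_correct = det_total = 0
    cells: dict[tuple[str, str], int] = {}
    non_empty = 0
    for f in frames:
        if f.is_empty:
            continue
        non_empty += 1
        all_ok = True
        for d in f.detections:
            if d.detection_id not in truth_labels:
                raise CoverageError(
                    f"no ground truth for detection {d.detection_id}"
                )
            true = truth_labels[d.detection_id]
            pred = predicted_labels.get(d.detection_id, UNKNOWN_LABEL)
            cells[(true, pred)] = cells.get((true, pred), 0) + 1
            det_total += 1
            if pred == true:
                det_correct += 1
            else:
                all_ok = False
        if all_ok:
            n_correct += 1
        else:
            n_incorrect += 1

    true_labels = sorted({t for t, _ in cells} | set(truth_labels.values()))
    pred_labels = sorted({p for _, p in cells} | set(true_labels))
    counts = pd.DataFrame(0, index=true_labels, columns=pred_labels, dtype=int)
    for (t, p), c in cells.items():
        counts.loc[t, p] = c
    score = VideoScore(
        video_id=video_id, N=N, cases=cases, cases_excl_empty=non_empty,
        n_correct=n_correct, n_incorrect=n_incorrect,
        detection_accuracy=(None if det_total == 0
                            else 100.0 * det_correct / det_total),
    )
    return score, ConfusionMatrix(counts)


def sample_frames(frames: list[FrameRecord], n: int, seed: int,
                  ) -> list[FrameRecord]:
    """Uniform sample of n frames without replacement, in frame order."""
    if n > len(frames):
        raise SamplingError(f"requested {n} of {len(frames)} frames")
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(frames), size=n, replace=False).tolist())
    return [frames[i] for i in idx]


def summarize_by_N(video_scores: list[VideoScore]) -> pd.DataFrame:
    """Per-N group summary plus an overall row.

    Count columns are sums; median accuracy uses the midpoint-of-two
    convention for even video counts. Videos with undefined accuracy are
    excluded from the median.
    """
    rows = []
    by_n: dict[int, list[VideoScore]] = {}
    for s in video_scores:
        by_n.setdefault(s.N, []).append(s)

    def summarize(group: list[VideoScore], label) -> dict:
        accs = [s.accuracy for s in group if s.accuracy is not None]
        return {
            "N": label,
            "videos": len(group),
            "cases": sum(s.cases for s in group),
            "cases_excl_empty": sum(s.cases_excl_empty for s in group),
            "n_correct": sum(s.n_correct for s in group),
            "n_incorrect": sum(s.n_incorrect for s in group),
            "median_accuracy": statistics.median(accs) if accs else None,
        }

    for n in sorted(by_n):
        rows.append(summarize(by_n[n], n))
    rows.append(summarize(video_scores, "overall"))
    return pd.DataFrame(rows)


def audit_tracks(track_rows: list[tuple[int, int, BoundingBox]],
                 ground_truth_N: int) -> TrackAudit:
    """Count distinct track ids against the true number of individuals."""
    ids = {track_id for _, track_id, _ in track_rows}
    return TrackAudit(ground_truth_N=ground_truth_N, detected_unique_ids=len(ids))


# ---------------------------------------------------------------------------
# helpers for scoring clusterings against scenario truth
# ---------------------------------------------------------------------------

def match_clusters_to_truth(assignments: list[IdentityAssignment],
                            truth: dict[int, int]) -> dict[int, int]:
    """Best bijection cluster -> true identity, maximizing agreement.

    Standard unsupervised-accuracy convention: build the cluster-by-identity
    contingency table and solve the maximum-agreement assignment.
    """
    clusters = sorted({a.cluster for a in assignments if a.cluster is not None})
    identities = sorted(set(truth.values()))
    table = np.zeros((len(clusters), len(identities)))
    c_index = {c: i for i, c in enumerate(clusters)}
    i_index = {k: i for i, k in enumerate(identities)}
    for a in assignments:
        if a.cluster is None:
            continue
        table[c_index[a.cluster], i_index[truth[a.detection_id]]] += 1
    rows, cols = linear_sum_assignment(-table)
    return {clusters[r]: identities[c] for r, c in zip(rows, cols)}
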