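"""Readers/writers for the on-disk formats and the perception backend contract.

Formats
-------
detections.jsonl
    First line is a session header ``{"n_frames": int, "embedding_dim": int}``;
    each subsequent line is one detection:
    ``{"frame": int, "detection_id": int, "box": [x_min, y_min, w, h],
    "confidence": float, "mask_coverage": float|null, "embedding": [...]|null}``.
skeletons.json
    ``{"frames": [{"frame": int, "people": [{"detection_id": int,
    "pose_keypoints_2d": [75 floats]}]}]}`` — flattened (x, y, c) triplets.
tracks.csv
    10-column MOTChallenge layout with 1-based frame numbers
    (frame, id, bb_left, bb_top, bb_width, bb_height, conf, x, y, z).
labels.csv
    columns session_id, frame, identity, pose_label in {sitting, standing}.

All writers are deterministic functions of the parsed values, so every
read/write pair is a byte-stable round trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import numpy as np
import pandas as pd

from .errors import (
    BackendError,
    DimensionError,
    FormatParseError,
    MissingReferenceError,
    ValidationError,
)
from .types import N_KEYPOINTS, BoundingBox, Detection, FrameRecord, Skeleton

POSE_LABELS = ("sitting", "standing")


@dataclass
class DetectionSession:
    """Frames of one session plus the header metadata, list-like over frames."""

    frames: list[FrameRecord]
    n_frames: int
    embedding_dim: int | None

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    @property
    def detections(self) -> list[Detection]:
        return [d for f in self.frames for d in f.detections]


# ---------------------------------------------------------------------------
# detections.jsonl
# ---------------------------------------------------------------------------

def read_detections(path) -> DetectionSession:
    """Parse a detections.jsonl file into ordered frames (empty frames included).

    Raises :class:`FormatParseError` with a line number on malformed JSON and
    :class:`DimensionError` naming the offending detection on a dimension
    mismatch against the header.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        return DetectionSession(frames=[], n_frames=0, embedding_dim=None)

    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as e:
        raise FormatParseError(f"{path}: line 1: invalid JSON header: {e}") from e
    if "n_frames" not in header:
        raise FormatParseError(f"{path}: header must declare n_frames")
    n_frames = int(header["n_frames"])
    embedding_dim = header.get("embedding_dim")

    by_frame: dict[int, list[Detection]] = {}
    max_frame = -1
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as e:
            raise FormatParseError(f"{path}: line {lineno}: {e}") from e
        try:
            frame = int(obj["frame"])
            det_id = int(obj["detection_id"])
            x, y, w, h = obj["box"]
            conf = float(obj["confidence"])
        except (KeyError, TypeError, ValueError) as e:
            raise FormatParseError(f"{path}: line {lineno}: bad record: {e}") from e
        emb = obj.get("embedding")
        if emb is not None:
            emb = np.asarray(emb, dtype=float)
            if embedding_dim is not None and emb.shape[0] != embedding_dim:
                raise DimensionError(
                    f"detection {det_id}: embedding has dimension "
                    f"{emb.shape[0]}, session declares {embedding_dim}"
                )
        det = Detection(
            detection_id=det_id,
            box=BoundingBox(frame, x, y, w, h, conf),
            mask_coverage=obj.get("mask_coverage"),
            embedding=emb,
        )
        by_frame.setdefault(frame, []).append(det)
        max_frame = max(max_frame, frame)

    total = max(n_frames, max_frame + 1)
    frames = [FrameRecord(i, by_frame.get(i, [])) for i in range(total)]
    return DetectionSession(frames=frames, n_frames=total, embedding_dim=embedding_dim)


def write_detections(session, path, embedding_dim: int | None = None) -> None:
    """Write frames as detections.jsonl; accepts a DetectionSession or frame list."""
    if isinstance(session, DetectionSession):
        frames = session.frames
        if embedding_dim is None:
            embedding_dim = session.embedding_dim
    else:
        frames = list(session)
    if embedding_dim is None:
        for f in frames:
            for d in f.detections:
                if d.embedding is not None:
                    embedding_dim = int(d.embedding.shape[0])
                    break
            if embedding_dim is not None:
                break
    n_frames = (max(f.frame_index for f in frames) + 1) if frames else 0

    out = [json.dumps({"n_frames": n_frames, "embedding_dim": embedding_dim})]
    for f in sorted(frames, key=lambda fr: fr.frame_index):
        for d in f.detections:
            out.append(json.dumps({
                "frame": f.frame_index,
                "detection_id": d.detection_id,
                "box": [d.box.x_min, d.box.y_min, d.box.width, d.box.height],
                "confidence": d.box.confidence,
                "mask_coverage": d.mask_coverage,
                "embedding": None if d.embedding is None else d.embedding.tolist(),
            }))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# skeletons.json
# ---------------------------------------------------------------------------

def read_skeletons(path, patch_offsets: dict[int, tuple[float, float]] | None = None,
                   ) -> list[Skeleton]:
    """Parse an OpenPose-dialect skeleton file into full-frame Skeletons.

    ``patch_offsets`` maps detection_id to the (x_min, y_min) patch origin;
    when given, patch-local coordinates are translated into the full frame.
    Confidence-0 keypoints are never translated. Without offsets, coordinates
    are taken to be full-frame already.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise FormatParseError(f"{path}: invalid JSON: {e}") from e

    skeletons: list[Skeleton] = []
    for frame_obj in doc.get("frames", []):
        frame = int(frame_obj["frame"])
        for person in frame_obj.get("people", []):
            det_id = int(person["detection_id"])
            flat = person["pose_keypoints_2d"]
            if len(flat) != 3 * N_KEYPOINTS:
                raise FormatParseError(
                    f"{path}: detection {det_id}: expected {3 * N_KEYPOINTS} "
                    f"keypoint values, got {len(flat)}"
                )
            kp = np.asarray(flat, dtype=float).reshape(N_KEYPOINTS, 3)
            sk = Skeleton(det_id, kp, frame_index=frame)
            if patch_offsets is not None:
                if det_id not in patch_offsets:
                    raise MissingReferenceError(
                        f"detection {det_id} absent from patch_offsets"
                    )
                ox, oy = patch_offsets[det_id]
                sk = sk.translated(ox, oy)
            skeletons.append(sk)
    return skeletons


def write_skeletons(skeletons: Sequence[Skeleton], path) -> None:
    """Write skeletons grouped by frame in the OpenPose-dialect layout."""
    by_frame: dict[int, list[Skeleton]] = {}
    for sk in skeletons:
        if sk.frame_index is None:
            raise ValidationError(
                f"skeleton for detection {sk.detection_id} has no frame_index"
            )
        by_frame.setdefault(sk.frame_index, []).append(sk)
    doc = {"frames": [
        {"frame": frame,
         "people": [{"detection_id": sk.detection_id,
                     "pose_keypoints_2d": [float(v) for v in sk.keypoints.ravel()]}
                    for sk in people]}
        for frame, people in sorted(by_frame.items())
    ]}
    Path(path).write_text(json.dumps(doc) + "\n")


# ---------------------------------------------------------------------------
# MOTChallenge tracks.csv
# ---------------------------------------------------------------------------

def read_tracks_mot(path) -> list[tuple[int, int, BoundingBox]]:
    """Parse a MOT CSV into (frame_index, track_id, box) rows, 0-based frames."""
    rows: list[tuple[int, int, BoundingBox]] = []
    for rowno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 10:
            raise FormatParseError(f"row {rowno}: expected 10 fields, got {len(parts)}")
        try:
            frame = int(float(parts[0]))
            track_id = int(float(parts[1]))
            left, top, w, h, conf = (float(p) for p in parts[2:7])
        except ValueError as e:
            raise FormatParseError(f"row {rowno}: non-numeric field: {e}") from e
        box = BoundingBox(frame - 1, left, top, w, h, min(max(conf, 0.0), 1.0))
        rows.append((frame - 1, track_id, box))
    return rows


def write_tracks_mot(rows: Iterable[tuple[int, int, BoundingBox]], path) -> None:
    """Write (frame_index, track_id, box) rows as 1-based MOT CSV."""
    lines = []
    for frame, track_id, box in rows:
        lines.append(
            f"{frame + 1},{track_id},{box.x_min!r},{box.y_min!r},"
            f"{box.width!r},{box.height!r},{box.confidence!r},-1,-1,-1"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# labels.csv
# ---------------------------------------------------------------------------

def read_labels(path) -> pd.DataFrame:
    """Read a pose ground-truth table; validates columns and label values."""
    df = pd.read_csv(path)
    required = ["session_id", "frame", "identity", "pose_label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatParseError(f"{path}: missing columns {missing}")
    bad = set(df["pose_label"]) - set(POSE_LABELS)
    if bad:
        raise FormatParseError(f"{path}: unknown pose labels {sorted(bad)}")
    return df[required]


def write_labels(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Perception backend contract
# ---------------------------------------------------------------------------

class PerceptionBackend(Protocol):
    """Pluggable per-frame perception stack.

    Stage order is detect -> crop -> mask -> estimate_pose / embed. Real
    deep-model adapters (person detector, segmentation masker, pose
    estimator, appearance embedder) implement this protocol; the synthetic
    replay backend is the reference implementation used by the test suite.
    """

    def detect(self, frame) -> list[BoundingBox]: ...

    def crop(self, frame, box: BoundingBox): ...

    def mask(self, patch): ...

    def estimate_pose(self, masked_patch) -> np.ndarray | None:
        """Patch-local (25, 3) keypoints, or None if no skeleton."""
        ...

    def embed(self, masked_patch) -> np.ndarray: ...


def run_perception(backend: PerceptionBackend, frame_source: Iterable,
                   embedding_dim: int | None = None) -> DetectionSession:
    """Run the full perception stack over a frame source.

    Produces one embedding and at most one skeleton per detection, skeletons
    already translated to full-frame coordinates. Deterministic for a
    deterministic backend. Backend exceptions are wrapped with frame context.
    """
    frames: list[FrameRecord] = []
    next_id = 0
    for frame_index, frame in enumerate(frame_source):
        try:
            boxes = backend.detect(frame)
            dets: list[Detection] = []
            for box in boxes:
                patch = backend.crop(frame, box)
                masked = backend.mask(patch)
                kp = backend.estimate_pose(masked)
                vec = np.asarray(backend.embed(masked), dtype=float)
                if embedding_dim is None:
                    embedding_dim = int(vec.shape[0])
                elif vec.shape[0] != embedding_dim:
                    raise DimensionError(
                        f"backend returned embedding of dimension {vec.shape[0]}, "
                        f"expected {embedding_dim}"
                    )
                sk = None
                if kp is not None:
                    sk = Skeleton(next_id, np.asarray(kp, dtype=float),
                                  frame_index=frame_index)
                    sk = sk.translated(box.x_min, box.y_min)
                dets.append(Detection(next_id, box, embedding=vec, skeleton=sk))
                next_id += 1
            frames.append(FrameRecord(frame_index, dets))
        except DimensionError:
            raise
        except Exception as e:  # noqa: BLE001 - contract: wrap with frame context
            raise BackendError(frame_index, str(e)) from e
    return DetectionSession(frames=frames, n_frames=len(frames),
                            embedding_dim=embedding_dim)


class ScenarioReplayBackend:
    """Backend that replays a synthetic SessionScenario.

    ``detect`` returns the scenario's stored boxes for the frame (the frame
    object is simply its index); ``embed`` returns the stored embedding; the
    pose stage returns the stored skeleton in patch-local coordinates when
    one was attached, so that run_perception reproduces the scenario exactly.
    """

    def __init__(self, scenario, skeletons: dict[int, Skeleton] | None = None):
        self.scenario = scenario
        self.skeletons = skeletons or {}
        self._by_box: dict[int, Detection] = {}
        for fr in scenario.frames:
            for det in fr.detections:
                self._by_box[id(det.box)] = det

    @property
    def frame_source(self):
        return range(len(self.scenario.frames))

    def detect(self, frame) -> list[BoundingBox]:
        return [d.box for d in self.scenario.frames[frame].detections]

    def crop(self, frame, box):
        return self._by_box[id(box)]

    def mask(self, patch):
        return patch

    def estimate_pose(self, masked_patch):
        det = masked_patch
        sk = self.skeletons.get(det.detection_id)
        if sk is None:
            return None
        # stored skeletons are full-frame; hand back patch-local coordinates
        return sk.translated(-det.box.x_min, -det.box.y_min).keypoints

    def embed(self, masked_patch):
        return masked_patch.embedding.copy()
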