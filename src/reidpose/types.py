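"""Domain types shared by every stage of the pipeline.

Coordinate convention: all pixel coordinates are full-image, origin at the
top-left corner, y increasing downward. Bounding boxes are stored as
(x_min, y_min, width, height) floats, matching the MOTChallenge layout.
Frame indices are 0-based internally; the MOT on-disk format is 1-based and
converted at the file boundary only.

Skeletons follow the 25-keypoint body layout (the BODY_25 convention of
flattened-triplet skeleton JSON). A missing keypoint is encoded with
confidence 0; its coordinates are ignored by every consumer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Canonical 25-keypoint body layout. Index order is load-bearing: the
#: anchors used throughout the package are Nose=0, Neck=1 and MidHip=8.
BODY25_NAMES: tuple[str, ...] = (
    "Nose", "Neck",
    "RShoulder", "RElbow", "RWrist",
    "LShoulder", "LElbow", "LWrist",
    "MidHip",
    "RHip", "RKnee", "RAnkle",
    "LHip", "LKnee", "LAnkle",
    "REye", "LEye", "REar", "LEar",
    "LBigToe", "LSmallToe", "LHeel",
    "RBigToe", "RSmallToe", "RHeel",
)

N_KEYPOINTS = 25

NOSE, NECK = 0, 1
RSHOULDER, RELBOW, RWRIST = 2, 3, 4
LSHOULDER, LELBOW, LWRIST = 5, 6, 7
MIDHIP = 8
RHIP, RKNEE, RANKLE = 9, 10, 11
LHIP, LKNEE, LANKLE = 12, 13, 14
REYE, LEYE, REAR, LEAR = 15, 16, 17, 18
LBIGTOE, LSMALLTOE, LHEEL = 19, 20, 21
RBIGTOE, RSMALLTOE, RHEEL = 22, 23, 24


@dataclass
class BoundingBox:
    """Axis-aligned person box in full-frame pixel coordinates."""

    frame_index: int
    x_min: float
    y_min: float
    width: float
    height: float
    confidence: float = 1.0

    def __post_init__(self):
        if self.frame_index < 0:
            raise ValidationError(f"frame_index must be >= 0, got {self.frame_index}")
        if not (self.width > 0 and self.height > 0):
            raise ValidationError(
                f"box width/height must be positive, got {self.width}x{self.height}"
            )
        if not 0.0 <= self.confidence <= 1.0:
            raise ValidationError(f"confidence must be in [0,1], got {self.confidence}")

    @property
    def cx(self) -> float:
        return self.x_min + self.width / 2.0

    @property
    def cy(self) -> float:
        return self.y_min + self.height / 2.0


@dataclass
class Skeleton:
    """25 named keypoints as an array of (x, y, confidence) rows.

    Coordinates are full-frame pixels. ``confidence == 0`` marks a missing
    keypoint whose coordinates carry no information.
    """

    detection_id: int
    keypoints: np.ndarray  # shape (25, 3)
    frame_index: int | None = None

    def __post_init__(self):
        kp = np.asarray(self.keypoints, dtype=float)
        if kp.shape != (N_KEYPOINTS, 3):
            raise ValidationError(
                f"skeleton must have shape (25, 3), got {kp.shape}"
            )
        conf = kp[:, 2]
        if np.any(conf < 0) or np.any(conf > 1):
            raise ValidationError("keypoint confidences must lie in [0, 1]")
        self.keypoints = kp

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask, True where the keypoint is absent."""
        return self.keypoints[:, 2] == 0.0

    def present(self, index: int) -> bool:
        return self.keypoints[index, 2] > 0.0

    def translated(self, dx: float, dy: float) -> "Skeleton":
        """Shift present keypoints by (dx, dy); missing ones stay untouched."""
        kp = self.keypoints.copy()
        live = ~self.missing
        kp[live, 0] += dx
        kp[live, 1] += dy
        return Skeleton(self.detection_id, kp, self.frame_index)


@dataclass
class Detection:
    """One person candidate in one frame."""

    detection_id: int
    box: BoundingBox
    mask_coverage: float | None = None
    embedding: np.ndarray | None = None
    skeleton: Skeleton | None = None

    def __post_init__(self):
        if self.mask_coverage is not None and not 0.0 <= self.mask_coverage <= 1.0:
            raise ValidationError(
                f"mask_coverage must be in [0,1], got {self.mask_coverage}"
            )
        if self.embedding is not None:
            v = np.asarray(self.embedding, dtype=float)
            if v.ndim != 1:
                raise ValidationError("embedding must be a 1-D vector")
            if not np.all(np.isfinite(v)):
                raise ValidationError(
                    f"embedding for detection {self.detection_id} has non-finite values"
                )
            self.embedding = v


@dataclass
class EmbeddingRecord:
    """Appearance vector tied to one detection (sidecar view of Detection.embedding)."""

    detection_id: int
    vector: np.ndarray


@dataclass
class FrameRecord:
    """All detections of one frame; empty list means an empty frame."""

    frame_index: int
    detections: list[Detection] = field(default_factory=list)

    def __post_init__(self):
        for d in self.detections:
            if d.box.frame_index != self.frame_index:
                raise ValidationError(
                    f"detection {d.detection_id} carries frame "
                    f"{d.box.frame_index}, expected {self.frame_index}"
                )

    @property
    def is_empty(self) -> bool:
        return len(self.detections) == 0
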