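"""Offline re-identification by fixed-K clustering of appearance embeddings.

The whole session's embeddings are clustered at once into exactly K groups
(K = the known number of unique individuals) — there is no real-time
constraint, so every appearance sample of every individual informs the
cluster structure. Assignments are then made per frame under the constraint
that no two detections in one frame may share an identity:

* ``flag`` mode assigns each detection to its nearest centroid
  independently and marks every detection involved in a same-frame cluster
  collision as conflicted (identity withheld).
* ``optimal`` mode resolves each frame with a minimum-total-squared-distance
  one-to-one assignment (Hungarian algorithm); when a frame holds more
  detections than identities, the surplus worst-cost detections are
  conflicted.

Numeric cluster ids can finally be mapped to semantic labels (for example
"Therapist" / "Patient"); conflicted detections receive the reserved label
"UNKNOWN" and are dropped by downstream analytics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .errors import CardinalityError, DimensionError, MappingError, ValidationError
from .types import Detection, FrameRecord

#: Reserved label applied to conflicted detections.
UNKNOWN_LABEL = "UNKNOWN"


@dataclass
class ClusterModel:
    """Fitted fixed-K clustering of a session's embeddings."""

    K: int
    centroids: np.ndarray          # (K, d)
    inertia: float
    n_iter: int
    seed: int
    normalized: bool = False       # embeddings L2-normalized before fitting

    def __post_init__(self):
        if self.K < 1:
            raise ValidationError("K must be >= 1")
        if not np.all(np.isfinite(self.centroids)):
            raise ValidationError("centroids must be finite")
        if self.inertia < 0:
            raise ValidationError("inertia must be >= 0")


@dataclass
class IdentityAssignment:
    """Cluster decision for one detection."""

    detection_id: int
    frame_index: int
    cluster: int | None            # None == UNASSIGNED
    distance: float | None         # Euclidean distance to assigned centroid
    status: str                    # "assigned" | "conflicted"
    label: str | None = None

    def __post_init__(self):
        if self.status not in ("assigned", "conflicted"):
            raise ValidationError(f"unknown status {self.status!r}")
        if self.status == "conflicted" and self.cluster is not None:
            # flag-mode invariant; optimal mode never produces this state
            raise ValidationError("conflicted assignments must be UNASSIGNED")
        if self.distance is not None and self.distance < 0:
            raise ValidationError("distance must be >= 0")


def _l2_normalize(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=-1, keepdims=True)
    norms[norms == 0] = 1.0
    return x / norms


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def kmeanspp_init(points: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """Plain D²-sampling k-means++ seeding.

    The first centroid is uniform over the points; each subsequent centroid
    is a point drawn with probability proportional to its squared distance
    to the nearest centroid chosen so far. When all remaining squared
    distances are zero (duplicate points), the draw falls back to uniform
    over the not-yet-chosen indices.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if K > n:
        raise CardinalityError(f"cannot seed {K} centroids from {n} points")
    chosen = [int(rng.integers(n))]
    d2 = np.sum((pts - pts[chosen[0]]) ** 2, axis=1)
    for _ in range(1, K):
        total = d2.sum()
        if total > 0:
            idx = int(rng.choice(n, p=d2 / total))
        else:
            remaining = np.setdiff1d(np.arange(n), chosen)
            idx = int(rng.choice(remaining))
        chosen.append(idx)
        d2 = np.minimum(d2, np.sum((pts - pts[idx]) ** 2, axis=1))
    return pts[chosen].copy()


def fit_kmeans(embeddings: np.ndarray, K: int, seed: int = 0,
               tol: float = 1e-4, max_iter: int = 300,
               n_restarts: int = 10, normalize: bool = False) -> ClusterModel:
    """Lloyd k-means with k-means++ seeding, best of ``n_restarts`` by inertia.

    Matches the clustering stage of the original pipeline (tolerance 1e-4,
    300 maximum iterations); deterministic given ``seed``. Empty clusters
    are repaired by relocating the centroid to the highest-cost point.
    """
    X = np.asarray(embeddings, dtype=float)
    if X.ndim != 2:
        raise DimensionError(f"embeddings must be 2-D (n, d), got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValidationError("embeddings must be finite")
    if X.shape[0] < K:
        raise CardinalityError(f"need at least {K} embeddings, got {X.shape[0]}")
    if normalize:
        X = _l2_normalize(X)
    km = KMeans(n_clusters=K, init="k-means++", n_init=n_restarts,
                tol=tol, max_iter=max_iter, random_state=seed,
                algorithm="lloyd")
    km.fit(X)
    return ClusterModel(
        K=K,
        centroids=km.cluster_centers_.copy(),
        inertia=float(km.inertia_),
        n_iter=int(km.n_iter_),
        seed=seed,
        normalized=normalize,
    )


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

def hungarian_min_cost(cost_matrix: np.ndarray) -> tuple[np.ndarray, float]:
    """Minimum-cost injective row -> column assignment.

    Requires a rectangular matrix with rows <= columns and finite entries.
    Returns (column index per row, total cost).
    """
    C = np.asarray(cost_matrix, dtype=float)
    if C.ndim != 2:
        raise ValidationError("cost matrix must be 2-D")
    if C.shape[0] > C.shape[1]:
        raise ValidationError(
            f"cost matrix must have rows <= columns, got {C.shape}"
        )
    if not np.all(np.isfinite(C)):
        raise ValidationError("cost matrix must be finite")
    rows, cols = linear_sum_assignment(C)
    order = np.argsort(rows)
    return cols[order], float(C[rows, cols].sum())


def _embedding_matrix(detections: list[Detection], model: ClusterModel) -> np.ndarray:
    d = model.centroids.shape[1]
    vecs = []
    for det in detections:
        if det.embedding is None:
            raise ValidationError(f"detection {det.detection_id} has no embedding")
        if det.embedding.shape[0] != d:
            raise DimensionError(
                f"detection {det.detection_id}: embedding dimension "
                f"{det.embedding.shape[0]} != model dimension {d}"
            )
        vecs.append(det.embedding)
    X = np.asarray(vecs, dtype=float)
    if model.normalized:
        X = _l2_normalize(X)
    return X


def assign_frame(frame_detections: list[Detection], model: ClusterModel,
                 mode: str = "flag") -> list[IdentityAssignment]:
    """Assign the detections of one frame to clusters under uniqueness.

    See the module docstring for the two modes. Distances are Euclidean in
    the space the model was fitted in (normalized if the model was).
    """
    if mode not in ("flag", "optimal"):
        raise ValidationError(f"mode must be 'flag' or 'optimal', got {mode!r}")
    if not frame_detections:
        return []
    X = _embedding_matrix(frame_detections, model)
    frame_index = frame_detections[0].box.frame_index
    # (n_det, K) Euclidean distances
    dist = np.linalg.norm(X[:, None, :] - model.centroids[None, :, :], axis=-1)

    out: list[IdentityAssignment] = []
    if mode == "flag":
        nearest = np.argmin(dist, axis=1)
        counts = np.bincount(nearest, minlength=model.K)
        for i, det in enumerate(frame_detections):
            c = int(nearest[i])
            if counts[c] > 1:
                out.append(IdentityAssignment(det.detection_id, frame_index,
                                              None, None, "conflicted"))
            else:
                out.append(IdentityAssignment(det.detection_id, frame_index,
                                              c, float(dist[i, c]), "assigned"))
        return out

    # optimal mode: Hungarian on squared distances; scipy handles the
    # rectangular case and leaves the worst (n_det - K) rows unmatched.
    rows, cols = linear_sum_assignment(dist ** 2)
    matched = dict(zip(rows.tolist(), cols.tolist()))
    for i, det in enumerate(frame_detections):
        if i in matched:
            c = matched[i]
            out.append(IdentityAssignment(det.detection_id, frame_index,
                                          int(c), float(dist[i, c]), "assigned"))
        else:
            out.append(IdentityAssignment(det.detection_id, frame_index,
                                          None, None, "conflicted"))
    return out


# ---------------------------------------------------------------------------
# labelling
# ---------------------------------------------------------------------------

def validate_mapping(mapping: dict[int, str], K: int) -> None:
    """Check the cluster -> label map is injective with domain {0..K-1}."""
    if set(mapping) != set(range(K)):
        raise MappingError(
            f"mapping domain must be exactly 0..{K - 1}, got {sorted(mapping)}"
        )
    if len(set(mapping.values())) != K:
        raise MappingError("mapping must be injective (distinct labels)")
    if UNKNOWN_LABEL in mapping.values():
        raise MappingError(f"{UNKNOWN_LABEL!r} is a reserved label")


def apply_mapping(assignments: list[IdentityAssignment],
                  mapping: dict[int, str]) -> list[IdentityAssignment]:
    """Replace cluster ids by semantic labels; conflicted -> "UNKNOWN"."""
    K = max(mapping, default=-1) + 1
    validate_mapping(mapping, K)
    out = []
    for a in assignments:
        if a.status == "conflicted":
            label = UNKNOWN_LABEL
        else:
            if a.cluster not in mapping:
                raise MappingError(f"cluster {a.cluster} missing from mapping")
            label = mapping[a.cluster]
        out.append(IdentityAssignment(a.detection_id, a.frame_index, a.cluster,
                                      a.distance, a.status, label))
    return out


def identity_mapping(K: int) -> dict[int, str]:
    return {k: str(k) for k in range(K)}


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_reid(frames: list[FrameRecord], K: int, mode: str = "flag",
             mapping: dict[int, str] | None = None, seed: int = 0,
             n_restarts: int = 10, normalize: bool = True,
             ) -> tuple[list[IdentityAssignment], ClusterModel]:
    """Whole-session offline re-identification.

    Clusters ALL embeddings of the session (no sampling), then enforces
    per-frame uniqueness and applies the semantic mapping (defaulting to
    stringified cluster ids). Deterministic given ``seed``.
    """
    detections = [d for f in frames for d in f.detections]
    embeddings = []
    for d in detections:
        if d.embedding is None:
            raise ValidationError(f"detection {d.detection_id} has no embedding")
        embeddings.append(d.embedding)
    model = fit_kmeans(np.asarray(embeddings), K, seed=seed,
                       n_restarts=n_restarts, normalize=normalize)
    assignments: list[IdentityAssignment] = []
    for f in frames:
        assignments.extend(assign_frame(f.detections, model, mode=mode))
    mapping = mapping if mapping is not None else identity_mapping(K)
    return apply_mapping(assignments, mapping), model
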