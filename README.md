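# reidpose

Offline multi-person **re-identification**, **sit/stand pose
classification** and **behavioural analytics** for long video recordings of
freely moving people — the setting of naturalistic observation studies
(for example children and therapists in a classroom), where individuals
repeatedly leave and re-enter the camera's field of view and generic
trackers fragment them into ever-new identities.

## The approach

Conventional online trackers must commit to identities frame by frame, so a
sustained occlusion usually spawns a brand-new track ("over-detection").
This package instead exploits two facts of the offline setting:

1. **The number of unique individuals K is known in advance.**
2. **There is no real-time constraint**, so the appearance evidence of the
   *entire* session can be used at once.

Given per-frame person detections with appearance-embedding vectors
x_i ∈ ℝ^d (produced by any detector/embedder behind a pluggable backend
contract, or by the in-repo synthetic generator), the pipeline:

- clusters **all** session embeddings into exactly K groups with k-means
  (k-means++ seeding, restarts, tol 1e-4, 300 max iterations),
- enforces **per-frame uniqueness** — no two detections in one frame may
  carry the same identity. In *flag* mode, all detections in a same-frame
  cluster collision are marked conflicted (reserved label `UNKNOWN`);
  in *optimal* mode each frame is resolved by a minimum-cost one-to-one
  assignment (Hungarian algorithm),
- optionally maps cluster ids to semantic labels (e.g. `Therapist`,
  `Patient`).

Downstream, 25-keypoint skeletons (BODY_25 layout, missing keypoints at
confidence 0) feed a gradient-boosted sitting/standing classifier
(translation/scale-invariant features; leave-one-session-out evaluation
with frame-weighted precision/recall/F1), and behavioural measures:
bounding-box centroid trajectories, sit/stand event intervals, and the
per-session neck-joint variance var(X)+var(Y) over sitting frames, with an
OLS trend test across sessions.

Everything is testable without video: the `simulate` module generates
sessions with K appearance centroids plus Gaussian noise, a two-state
Markov presence process (occlusions/re-entries), reflected-random-walk box
motion, and geometrically distinct sitting/standing stick figures.

## Worked example

```bash
reidpose simulate --k 3 --n-frames 500 --noise-sigma 1.0 --seed 1 --out session
reidpose reid session/detections.jsonl --k 3 --seed 1 --out reid
reidpose evaluate reid/assignments.csv session/truth.csv \
    session/detections.jsonl --out eval
cat eval/score.json
```

prints

```json
{
  "N": 3,
  "cases": 500,
  "cases_excl_empty": 498,
  "n_correct": 498,
  "n_incorrect": 0,
  "accuracy_pct": 100.0,
  "detection_accuracy_pct": 100.0
}
```

Of 500 frames, 2 were empty (all three people absent) and are excluded
from the accuracy denominator; every remaining frame had all of its
detections labelled correctly, i.e. 100% frame accuracy at a
separation-to-noise ratio of 10. Auditing the re-identification output as
a track file confirms no identity fragmentation:

```bash
reidpose audit-tracks reid/tracks.csv --n 3
# {"ground_truth_N": 3, "detected_unique_ids": 3, "difference": 0}
```

A fragmented tracker output over the same two-person session would audit
to a positive `difference` (extra identities).

Other subcommands: `pose-train` / `pose-predict` (sit/stand classifier)
and `analyze` (trajectories, event intervals, neck-joint variance). Every
run writes a `manifest.json` with the config, seed, version and input
checksums.

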