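# Methods

This note documents the models and procedures implemented in `reidpose`,
the parameter defaults and why they were chosen, what the synthetic data
generator does and does not emulate, and the numerical/design decisions
that were genuinely open.

## Re-identification model

Each detection *i* carries an appearance embedding x_i ∈ ℝ^d. The model
assumes embeddings of one individual concentrate around an
individual-specific centroid, so with the number of unique individuals K
known, identity recovery is fixed-K clustering of the *whole session's*
embeddings:

- `fit_kmeans`: Lloyd k-means, k-means++ seeding, best of `n_restarts`
  (default 10) by inertia, tolerance 1e-4, 300 max iterations (the
  scikit-learn implementation; its empty-cluster repair relocates a
  centroid to the highest-cost point). `kmeanspp_init` is also exposed as
  the textbook D²-sampling seeder, whose sampling distribution the tests
  verify exactly — scikit-learn internally uses the greedy variant with
  local trials, which is an optimisation of the same idea.
- **Per-frame uniqueness.** *flag* mode assigns each detection to its
  nearest centroid independently; if two or more detections of a frame
  land in one cluster, *all* of them are marked conflicted and receive the
  reserved label `UNKNOWN`. With no principled tiebreak available,
  symmetric treatment is the only defensible rule; conflicted detections
  are dropped by downstream analytics. *optimal* mode instead solves the
  frame's minimum-total-squared-distance one-to-one assignment
  (`scipy.optimize.linear_sum_assignment`); with more detections than
  identities the surplus worst-cost detections are conflicted.
- **L2 normalization** of embeddings before clustering is the default
  (appearance-embedding similarity is conventionally cosine-like), with a
  flag to disable. Note that normalization rescales distances, so
  experiments phrased in raw embedding units (below) disable it.

## Synthetic session generator

`simulate_session` emulates the recording setting, not its pixels:

| parameter | default | meaning |
|---|---|---|
| K | 2 | unique individuals (1–8) |
| n_frames | 2000 | session length |
| embedding_dim d | 64 | appearance-embedding dimension |
| centroid_separation | 10.0 | min pairwise centroid distance (embedding units) |
| noise_sigma | 1.0 | isotropic embedding noise std |
| enter_prob a / exit_prob b | 0.2 / 0.05 | presence-chain transition probabilities |
| image_size | 1280×720 | pixels |
| motion_sigma | 5.0 | box-centre random-walk step std (px) |

Centroids are Gaussian draws rescaled so the minimum pairwise distance
equals `centroid_separation`; an optional *confusable pair* is pulled to
exactly its reduced separation, modelling two people wearing similar
clothing. Presence is an independent two-state Markov chain per identity,
started present, with long-run present fraction a/(a+b) = 0.8 under the
defaults (mean visible bout 1/b = 20 frames, mean absence 1/a = 5 frames);
the occlusion statistics of real sessions are unknown, so these values are
deliberately exposed rather than claimed realistic. The ratio
separation/σ is the single difficulty knob. d = 64 keeps the geometry of
high-dimensional appearance embeddings (noise norm ≈ σ√d ≫ σ) while
staying fast; the on-disk default for real backends is d = 512.

What the generator does **not** emulate: embedding distribution shift over
time (lighting, pose), detector misses and false positives correlated with
occlusion, non-isotropic appearance noise, box-size changes with depth.
Perfect scores on synthetic separable sessions therefore demonstrate
correctness of the machinery, not expected accuracy on real video.

The 25-keypoint layout (`reidpose.types.BODY25_NAMES`) is, in index
order: Nose 0, Neck 1, RShoulder 2, RElbow 3, RWrist 4, LShoulder 5,
LElbow 6, LWrist 7, MidHip 8, RHip 9, RKnee 10, RAnkle 11, LHip 12,
LKnee 13, LAnkle 14, REye 15, LEye 16, REar 17, LEar 18, LBigToe 19,
LSmallToe 20, LHeel 21, RBigToe 22, RSmallToe 23, RHeel 24. The anchors
used throughout are Nose = 0, Neck = 1 and MidHip = 8; skeleton files
store flattened (x, y, confidence) triplets in this order.

`simulate_skeleton` builds 25-keypoint stick figures: standing draws the
hip–knee–ankle angle in [165°, 180°] (MidHip-to-ankle vertical extent
≈ 2 torso lengths), sitting in [80°, 100°] (extent ≈ 1 torso, thighs
horizontal); per-keypoint Gaussian pixel noise and independent dropout
(confidence 0) follow. With zero noise a 130° knee-angle threshold
separates the classes perfectly, which anchors the classifier tests.

## Pose classification

Features per skeleton: all 25 keypoints centred on MidHip and divided by
the torso (Neck–MidHip) length, five angles in degrees (left/right knee,
left/right hip, trunk inclination from vertical) and 25 missingness bits
(80 features, schema version 1). Missing keypoints contribute zero
coordinates; angles with a missing input are reported as 0 and the bits
let the trees condition on it. Skeletons missing an anchor (Neck or
MidHip) are skipped at training time and labelled `UNSCORED` at prediction
time — imputation would inject pose information the estimator never
observed. The classifier is XGBoost with default hyperparameters (no
tuning). Evaluation is leave-one-session-out; the summary
precision/recall/F1 per class are means across folds weighted by the
held-out frame count. In the cross-validation experiment the corpus is 10
sessions × 500 frames with 6 px keypoint noise on 100 px limbs (≈ 5° of
knee-angle jitter, since σ_angle ≈ √2·σ_px/T) and 10% keypoint dropout.

## Behavioural analytics

- **Centroid tracks**: (cx, cy) = (x_min + w/2, y_min + h/2) per frame per
  label; absences leave gaps, never interpolated.
- **Event intervals**: maximal constant-label runs; `UNSCORED` frames
  break runs. Runs shorter than `min_duration` (default 1 = no smoothing)
  are merged into the longer neighbouring run, preferring the preceding
  run on ties.
- **Joint variance**: var(X) + var(Y) with the sample (n−1) estimator over
  qualifying frames (joint present, and within the sitting-frame filter
  when given). Restricting to sitting frames prevents postural changes
  from inflating the neck-movement index.
- **Trend**: OLS of per-session variance on the session ordinal with a
  two-sided t-test on the slope (`method: ols_t` recorded so a rank-based
  alternative can be added); a zero-residual fit reports p = 0 with a
  degeneracy flag. Calibration experiments simulate per-session neck
  jitter directly as coordinate arrays and run them through the same
  variance estimator code (`joint_variance_from_xy`), avoiding millions of
  skeleton objects per replicate: type-I error sits at the nominal 5%
  under a constant-jitter null (1000 replicates, 10 sessions × 200
  frames, σ = 3 px) and power exceeds 90% when σ decays linearly from 4 px
  to 2 px.

## Scoring conventions

Frame accuracy excludes empty frames from the denominator and counts a
frame correct only if *every* detection in it is correctly labelled;
conflicted (`UNKNOWN`) predictions are incorrect. Detection-level accuracy
and a per-identity confusion matrix (detection granularity) are emitted
alongside. Group medians use the midpoint-of-two convention. Cluster ids
are matched to true identities with the maximum-agreement bijection
(Hungarian on the contingency table) before scoring — the standard
unsupervised-accuracy convention. `audit_tracks` reports the signed
difference between distinct track ids in a MOT file and the true number of
individuals.

## Validation experiment design (`reidpose.validation`)

Problem sizes were chosen for stable statistics at desk scale; all
randomness descends from one seed via `numpy.random.SeedSequence`.

- *Assignment oracle*: 200 random 5×5 cost matrices, solver vs exhaustive
  5! search — exact agreement expected.
- *Clustering oracle*: 100 instances of 10 points from a two-identity
  Gaussian mixture at 3σ separation, restarted Lloyd vs exhaustive
  minimum-SSE bipartition (2⁹ splits). The mixture instances mirror what
  the clustering stage ingests; on fully structureless clouds restarted
  Lloyd genuinely lands in a local optimum on ~5–8% of instances, which is
  a property of Lloyd's landscape rather than of this implementation.
- *Perfect recovery*: zero-noise sessions, K ∈ {2..5}, 2000 frames, 5
  seeds, both uniqueness modes — 100% frame accuracy, zero conflicts.
  (Zero noise makes L2 normalization irrelevant here.)
- *Confusable pair*: K = 4, pair at 1σ, others at 10σ. Error
  concentration is measured in optimal mode, which yields an identity for
  every detection and hence a complete predicted-vs-true confusion matrix;
  in flag mode the same failure surfaces as conflicts, reported
  separately. Normalization is disabled because the 1σ/10σ geometry is
  stated in raw units.
- *Degradation*: mean frame accuracy over 20 seeds per point on the
  separation grid {16, 8, 4, 2, 1}·σ (K = 3, 400 frames), expected
  non-increasing.
- *Centroid recovery*: the error norm of a d-dimensional Gaussian mean
  estimate concentrates at σ√(d/n_k), so fitted centroids are required to
  lie within 3σ√(d/n_k) of distinct true centroids — the d-dimensional
  three-sigma band; a 3σ/√n_k bound is its d = 1 specialisation and is not
  attainable at d = 64 for any estimator.
- *Over-detection worked examples*: MOT files with 6 and 7 distinct track
  ids for two-person sessions audit to differences +4 and +5.

## Known limitations

- K must be exact; the package does not estimate it, and a wrong K
  silently merges or splits identities.
- Flag mode withholds identities on collisions rather than arbitrating;
  sessions with many near-duplicate appearances lose coverage.
- The trend test assumes roughly independent, homoscedastic per-session
  variance estimates; heavy session-length imbalance violates this.
- Real-model perception backends (detector, masker, pose estimator,
  embedder) are interface stubs by design; only the synthetic backend is
  exercised by the test suite.
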