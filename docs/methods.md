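# Methods

This note documents the models and procedures `pearcount` implements, the
defaults and why they were chosen, what the synthetic data does and does not
emulate, and the numerical conventions that make runs reproducible.

## Coordinate and file conventions

All geometry is in pixels with the origin at the top-left corner, x
rightward, y downward; boxes are stored as (left, top, width, height) with a
centroid at (x + w/2, y + h/2). MOT-challenge files are 1-based in their
frame column on disk and re-based to 0 in memory. YOLO-dialect files carry
normalized center/size coordinates and need the frame size to denormalize;
their class column is ignored because the toolkit tracks a single object
class. Ground-truth boxes are clipped to the frame on construction, and
re-clipped after a read because text serialization rounds coordinates to six
significant digits.

## Detection evaluation

A detection is a true positive when it overlaps a ground-truth box at
IoU ≥ 0.5 (configurable) after discarding detections below a 0.25 confidence
threshold. Matching is the Pascal-VOC greedy protocol: detections are
visited in descending confidence (ties broken deterministically by frame,
then left, then top coordinate) and each claims its highest-IoU unclaimed
ground-truth box. Discarded low-confidence detections are neither TP nor
FP; the boxes they would have covered count as FN. Average precision is the
11-point interpolated form, AP = (1/11) Σ_{r ∈ {0, 0.1, …, 1}} max{P(R̃) :
R̃ ≥ r}, with the max over an empty set equal to 0. On near-one-to-one
instances (jittered copies of ground truth plus spurious boxes — the
geometry a real detector produces) greedy matching attains the
maximum-cardinality matching; the test suite verifies this against
exhaustive enumeration.

## Tracker

The tracker is an online tracking-by-detection design in the SORT/Deep-SORT
mold. Each track carries an 8-dimensional state (cx, cy, a, h) plus
per-frame derivatives under a constant-velocity model; process and
measurement noise scale with the object height through two weights
(`std_weight_position` = 1/20, `std_weight_velocity` = 1/160). Association
runs in two stages: a matching cascade over confirmed tracks in ascending
time-since-update, using the configured cost (1 − IoU, appearance cosine
distance against a bounded gallery of 100 embeddings, or a λ-blend with
λ = 0.5), gated by the squared Mahalanobis distance of the measurement at
the chi-square 0.95 quantile with 4 degrees of freedom; then a catch-all IoU
stage over everything unmatched. Unmatched detections spawn tentative
tracks; three consecutive hits confirm a track; a tentative track missed
once, or any track missed for more than `max_age` = 30 frames, is deleted.
Track identifiers are never reused, and the state after frame t depends only
on frames ≤ t (verified by a truncation test that demands byte-identical
history prefixes).

Two constants deliberately depart from the pedestrian-tracking convention,
both motivated by objects that enter and leave through the frame border:

* **Initial aspect-ratio standard deviation 0.5** (convention: 0.01). The
  first measurement of an entering object is border-clipped, so its w/h says
  little about the true shape. With a near-zero prior variance the filter
  keeps the sliver's aspect ratio for the track's whole life, its predicted
  box stays several times too wide, and every fruit fragments into multiple
  tracks at entry. A generous prior lets the first few full measurements
  correct the aspect.
* **IoU gate `max_iou_cost` = 0.85** (convention: 0.7). At an image flow of
  ~20 px/frame on ~100 px objects, a track that misses a single frame during
  the clipped-entry phase overlaps its next detection by as little as ~0.2;
  the looser gate lets the catch-all stage reattach it. On 50-fruit
  simulated passes at 10 % flicker this change alone reduces the mean
  absolute unique-ID count error from ≈3.8 to ≈0.3 per pass, with no effect
  on clean-pass recovery. The catch-all stage also considers *all* unmatched
  tracks, not only those missed exactly once, for the same reason.

Kalman means are floored at aspect 10⁻³ and height 1 px: extrapolating a
heavily clipped box can otherwise drive the state negative.

## Counting

* **Unique IDs**: every track that was ever confirmed counts once. By
  default tentative-only tracks do not count (`count_only_confirmed`);
  counting them would make the tally hostage to single-frame noise.
* **ROI line**: a horizontal line at `roi_fraction` = 0.5 of the frame
  height. A track counts at the first history frame whose centroid is on
  the opposite side of the line from the previous off-line centroid;
  centroids exactly on the line resolve at the next off-line frame; each id
  counts at most once regardless of re-crossings, and an optional direction
  filter restricts to downward or upward crossings (default: either, since
  the capture geometry already fixes the flow direction). Crossing is
  evaluated on the full history *including* coast (predicted-only) frames —
  bridging detection dropouts is precisely the tracker's job here.
* **Lifespan filter**: unique-ID counting restricted to tracks whose
  detection coverage is at least `lifespan_fraction` = 0.8 (boundary
  included). Coverage is detected frames over the span from the first frame
  to the *last detected* frame: the up-to-`max_age` coast frames a track
  accumulates while waiting for deletion measure the deletion timer, not the
  object, and would otherwise dilute every track's coverage by a constant.

## Counting evaluation

Counted ids are matched to ground-truth objects greedily by mean IoU over
co-visible frames, admissible at ≥ `min_track_iou` = 0.3; matched ids are
TP, surplus ids FP, unclaimed objects FN. Two FP-rate conventions exist
in the literature: 1 − P_count (the detection-style complement) and
FP/total_gt. Only the latter satisfies MOTA = 1 − FN_rate − FP_rate at
mismatches = 0, and the published rate tables this package reproduces are
mutually consistent only under it, so it is the default; the complement is
available as `fp_rate_convention="complement"`. Mismatches (identity
switches) default to 0: the fruits are static, so a swap between two
stationary objects does not change the count. The F1/MOTA identities can
also be computed directly from printed percentage rates
(`counting_metrics_from_rates`) when the underlying integer counts are not
published.

The ROI-line miss breakdown classifies each counting FN by its associated
detections (IoU ≥ 0.5 with the object's box on the same frame):
`never_detected`, `detected_only_after_line` (all detections beyond the
line), `detected_near_line` (first detection within ±5 % of frame height
around the line), or `detected_other` (a tracking rather than detection
failure). The categories are exhaustive and mutually exclusive, in that
precedence order.

## Simulator

The generator emulates the study geometry this toolkit targets: a camera
carried along a row of trees filming from below, with fruits static in the
world, so camera motion renders as a constant vertical image flow and every
fruit enters at the top, crosses a horizontal counting line mid-pass, and
exits at the bottom. Defaults describe a portrait 1080 × 1920 phone video:
50 fruits of 60–140 px (width 0.8–1.05 × height, pears being roughly
square), image flow 20 px/frame, and a 17 280 px strip giving a ≈960-frame
pass (32 s at 30 FPS) with each fruit visible for ≈100 frames. The ideal
detector reports the frame-clipped box at confidence 1, but only once at
least `min_visibility` = 25 % of the fruit's area is inside the frame — real
detectors do not fire on a few-pixel border sliver.

The corruption model turns the ideal stream into realistic detector output;
all channels draw from independent child generators of one seed, so changing
one rate leaves the other channels' draws untouched and paired-seed
experiments stay paired:

| channel | default | meaning |
|---|---|---|
| `p_miss` | 0.1 | independent per fruit-frame dropout (flicker) |
| `occlusion_rate` / `occlusion_duration` | 0.35, 20–70 frames | per-fruit entry occlusion: the fruit emerges from foliage only after the episode |
| `jitter_sigma` | 2 px | Gaussian noise on box center, and on log-size scaled by 1/height |
| `fp_rate` | 0.2/frame | Poisson spurious boxes at uniform positions, fruit-sized |
| `confidence_true` / `confidence_false` | N(0.85, 0.08) / N(0.40, 0.15), clipped to [0, 1] | detector confidence models |
| `embedding_dim` / `embedding_noise` | 16, 0.1 | fixed random unit vector per fruit, observed with additive noise and renormalized; spurious boxes get fresh vectors |

Occlusion is anchored at the start of visibility rather than scattered
mid-track for two reasons. Scientifically, it is the failure mode that makes
a fruit *first* detectable near or beyond the counting line — the dominant
miss category for line-crossing counters — and in heavy foliage fruits do
tend to emerge partway through the pass. Structurally, mid-track occlusions
longer than `max_age` would fragment tracks and conflate the occlusion and
flicker effects that the degradation experiments hold apart.

What the simulator does *not* emulate: appearance (no rendering, so
detector confidence is uncorrelated with pose or lighting), correlated
misses between neighboring fruits, camera shake or speed variation,
fruit-on-fruit occlusion dynamics, and any detector-specific error
structure. Passing tests therefore demonstrate that the tracking, counting,
and evaluation machinery is correct and that the qualitative flicker/ROI
trade-off emerges from the geometry — not that any particular detector will
reach any particular accuracy on real video.

## Training utilities

* **Learning-rate schedule**: linear ramp to `lr0` over the first 1000
  iterations (reaching `lr0` exactly at the boundary), then piecewise
  constant with decade drops governed by the recurrence LR_{n+1} = d·LR_n
  when n is in `steps` = {4800, 5400}; a drop therefore takes effect
  strictly after its step iteration. Defaults: lr0 = 0.001, d = 0.1,
  max_iter = 6000.
* **Four-way split**: for studies that train on one capture source
  (high-resolution camera) and deploy on another (phone), the 70:10:10:10
  train / train-val / val / test split assigns high-resolution items to
  train and train-val only and phone items to val and test only. Target
  sizes come from largest-remainder rounding over the full set (ties by
  partition order); each source fills its first partition to target and
  overflows into its second, so sizes are exact whenever the source totals
  are compatible. Augmentation families (items sharing an original-image
  group key) are shuffled and placed whole — an augmented derivative in the
  validation set of its original's training run would leak. Too few phone
  items for val+test is an explicit error; items are never backfilled across
  sources.
* **Anchors**: k-means on (w, h) pairs under d = 1 − IoU of corner-anchored
  boxes, seeded k-means++ initialization, medoid center updates (the member
  minimizing its cluster's total distance). Medoids rather than means make
  the clustering a strict descent method under this non-Euclidean distance,
  which the tests assert; anchors are returned sorted by area. Medoid
  updates cost O(n²) per cluster, which is immaterial at anchor-clustering
  scales (thousands of boxes).
* **Error-gap report**: given APs on the four splits, stage B (train vs
  train-val) flags overfitting, C (train-val vs val) data mismatch between
  sources, D (val vs test) validation overfitting; stage A compares train AP
  to an optional target. A stage is `ok` when downstream AP drops by at
  most the tolerance (default 2 percentage points); a downstream *increase*
  is always favorable.

## Reproducibility and problem sizes

Every stochastic component takes an explicit integer seed and spawns
independent child generators; identical configurations produce
byte-identical artifacts, which the pipeline guarantees by always feeding
downstream stages from the serialized text files rather than in-memory
objects. The acceptance script derives all of its seeds from the single
`--seed` argument.

The recovery and degradation experiments use the simulator defaults
(50-fruit, ≈960-frame passes): one clean pass for exact-recovery, 20
replicates at `p_miss` = 0.1 for the counting-error estimate, and 10 paired
replicates at `p_miss` ∈ {0, 0.3} for the flicker-degradation ordering —
sizes at which the binomial noise on the reported means is well below the
effects being measured, while a full run of the suite plus the acceptance
script stays within a few minutes on one CPU.

## Known limitations

* The tracker's appearance model is consume-only: embeddings come from a
  file or the simulator, never from a CNN, so re-identification quality on
  real video depends entirely on the supplied vectors.
* Greedy VOC matching is not a maximum matching on adversarial geometries
  (a detection overlapping two ground-truth boxes above threshold while a
  second detection overlaps only one); it is standard practice and exact on
  detector-like instances, but the TP count can differ from the optimum on
  pathological inputs.
* The ROI counter assumes an essentially monotone flow; an oscillating
  camera would need the direction filter and possibly hysteresis, which is
  not implemented.
* `fn_breakdown` attributes misses from detections alone; it cannot
  distinguish a tracker that dropped a well-detected object from an
  association failure (`detected_other` covers both).
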