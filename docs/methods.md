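# Methods

## Motion model and filter

Tracks carry a Gaussian belief over `x = (cx, cy, a, h, v_cx, v_cy, v_a,
v_h)` — box center (px), aspect ratio (dimensionless), height (px) and
their per-frame velocities.  Dynamics are constant-velocity,
`x' = F x` with `F = [[I4, Δt·I4],[0, I4]]` and `Δt = 1` frame; the
observation is `z = H x`, `H = [I4 | 0]`.  Noise is isotropic and
time-invariant: initial covariance `P0 = 500·I8` (a new track knows its
position only to detector accuracy and its velocity not at all),
process noise `Q = 0.1·I8`, observation noise `R = 2·I4` (detector box
jitter of ~1.4 px std).  New tracks initiate with zero velocity.

The filter is a full unscented Kalman filter: Merwe-scaled sigma points
(`α = 1e-3`, `β = 2`, `κ = 0`; all configurable) propagated through the
transition/observation maps, which are accepted as arbitrary callables
so non-linear cell dynamics can be plugged in without touching the
tracker.  With the shipped linear model the UKF is mathematically
identical to a linear Kalman filter; the test suite exploits this by
checking predict/update against an independently coded textbook KF to
1e-6 relative error on 100 random states.  This equivalence is a
deliberate property, not an accident: the unscented machinery buys
generality, and the linear case provides an exact oracle.

Numerical choices: covariances are symmetrized `(P + Pᵀ)/2` after every
step; Cholesky factorization retries with diagonal jitter escalating
from 1e-9 by factors of 10 up to 1e-3 before raising; after every
predict/update the aspect-ratio and height components are floored at
1e-3 so the state always maps back to a valid box.  At `α = 1e-3` the
sigma weights have magnitude ~1e6, so weight normalization (and any
identity that cancels them) holds to machine precision *relative to the
weight magnitude* — about 1e-10 absolute — which is the conditioning
limit of float64, not an implementation defect.

## Appearance embeddings

The embedding contract: a backbone maps a crop (resized bilinearly to
128×128) to exactly three feature maps at strictly decreasing spatial
resolution; each is globally average-pooled per channel; the pooled
vectors are concatenated in scale order and L2-normalized.  Cosine
distance divides by both norms even though fused embeddings are already
unit vectors, so unnormalized inputs are handled gracefully.

The default backbone is a deterministic, training-free *toy backbone*:
the crop is block-averaged to 32×32, standardized per crop (zero mean,
unit variance — absolute intensity is discarded so the embedding
encodes texture and shape contrast), and non-overlapping patches (2×2,
4×4, 8×8) are projected through fixed random matrices drawn once from
the seed, followed by tanh.  A small bias column keeps constant
(e.g. all-black) crops embeddable.  Output scales are 16×16×8, 8×8×16,
4×4×32 by default.  This backbone verifies the pooling/fusion/distance
pipeline and separates visually distinct synthetic cells (pairwise
cosine distance ≳ 0.01–0.1); it is *not* a trained re-identification
feature and makes no claim of discriminating real cells.  An adapter
for a pretrained multi-stage convolutional backbone (e.g. ResNet50
tapped after its second, third and fourth stages) is the intended
production plug-in; it requires a deep-learning runtime and weights and
is therefore an extension point, not a bundled dependency.

## Association

Cost: `C[i,j] = λ·d²_motion + (1−λ)·d_cos` with `λ = 0.5` by default
(configurable; the endpoints recover pure-motion and pure-appearance
association).  `d_cos` is the minimum cosine distance to the track's
gallery (last 100 embeddings, oldest evicted).  When no frames are
available the tracker runs motion-only.  Gating marks pairs infeasible
when `d²_motion` exceeds the 95% χ² quantile with 4 degrees of freedom
(≈ 9.4877); an optional appearance gate (max cosine distance 0.4) can
be added.  Infeasible entries enter the Hungarian solver as a large
finite sentinel (1e5) and are filtered from the result, so the solver
never sees infinities.  Ties among equal-cost optima break toward the
lexicographically smallest (track, detection) pairs via an additive
perturbation several orders below any meaningful cost difference.

The matching cascade walks track age `a = 1..max_age` (frames since
last match) and solves build→gate→assign per level against the
still-unmatched detections, so recently seen tracks win contested
detections.  Bookkeeping detail: prediction increments
`time_since_update` and a match resets it to 0, so a track matched last
frame enters the cascade at age 1 — the net per-frame effect on
unmatched tracks is the conventional +1.  A fallback stage associates
tentative tracks and confirmed tracks missed exactly one frame by box
overlap (Hungarian on `1 − IoU`, threshold 0.3).

Association is class-agnostic: mitosis legitimately flips a cell
between the Cell and Division classes, so forbidding cross-class
matches would break tracks at exactly the biologically interesting
moment.  A track reports the class of its most recent matched
detection.

## Track lifecycle and gap-filling

`n_init = 3` consecutive hits confirm a tentative track (suppresses
spurious single-frame detections); a missed tentative dies immediately;
a confirmed track is deleted after `max_age = 30` missed frames.  While
a confirmed track is unmatched it emits its UKF-predicted box, flagged
`source=predicted`, for at most `max_coast = 5` consecutive frames —
unbounded coasting would fabricate boxes for cells that genuinely left
or died, so the budget bounds the false-box risk while still covering
transient detector failures.  Evaluation can include or exclude coasted
boxes (`--include-predicted`, default include).  Track ids are
sequential from 1 and never reused.  Division events are not modeled as
lineage: daughters simply start new tracks (lineage reconstruction is
out of scope).

## Evaluation metrics

Ground truth and predictions are matched per frame, greedily by
descending IoU with threshold 0.5, ties toward the lowest (gt, pred)
indices; the matching rule had to be chosen here since only the metric
formulas are fixed externally.  Modified Recall = `100·ΣTP/Σ(TP+FN)`
pooled over frames; unmatched predictions are ignored by construction,
which makes the metric appropriate for incompletely annotated data and
monotone non-decreasing under added predictions.  Average IoU is the
mean over matched pairs only, so it lies in (50, 100] at the default
threshold.  Identity switches count the frames where a ground-truth
object's matched predicted id differs from its previous one; the count
is invariant to bijective relabeling of predicted ids.  Metrics print
at 2 decimals; raw values are retained.  MOTA/MOTP/IDF1/HOTA and
precision/mAP are out of scope — they presuppose complete annotation.

## Synthetic data

The simulator emulates the statistical structure of the target imagery:
1600×1200 grayscale frames, 10–22 objects per frame, cells ~40 px high
(σ 8) with aspect ratio ~1.2 (σ 0.2), initial centers at least 80 px
apart (cultures are moderately sparse and mostly non-overlapping).
Motion is a heading-noise random walk — per-cell constant speed drawn
from 1–4 px/frame, heading perturbed by N(0, 0.3 rad) each frame,
reflecting walls — chosen *deliberately mismatched* to the tracker's
constant-velocity model so tests never evaluate the filter on its own
assumptions.  Divisions are rare (default 0.005 per cell per frame,
lasting 6 frames: together ≈ 3% of instances in the Division class,
mirroring the strong class imbalance of real annotations); a dividing
cell inflates its box 1.4× and rounds to aspect 1, then splits into two
daughters with fresh ids at the same frame its own id disappears.

The degradation stage models an imperfect detector: each box dropped
independently with probability `dropout_p`, survivors jittered with
Gaussian noise on center and size (σ 1 px default), confidence uniform
in [0.5, 1]; no false positives by default (an optional clutter rate
adds them for stress tests).  Rendering draws each cell as an
anisotropic Gaussian blob modulated by a fixed per-cell speckle texture
(its appearance signature) on a noisy gray background (level 100, σ 8),
with Division-class cells 1.3× brighter; a grayscale-inversion helper
mirrors the contrast augmentation used on real data.

What passing tests do and do not show: the simulator has no optics
(PSF, illumination drift), no cell deformation, no touching/overlapping
cells, and its dropout is independent per box rather than correlated
with crowding.  Results on it demonstrate the correctness of the
filtering, association, lifecycle and metric machinery and the
direction of the gap-filling effect — not performance on real
microscopy.

## Problem sizes

The verification suite uses sizes chosen to make the statistics stable:
gap-filling runs ten 100-frame sequences of 15 cells at 30% dropout
through the full pipeline (rendered frames + toy backbone); the
UKF/linear-KF comparison uses 100 random states; solver optimality uses
200 random cost matrices up to 6×6 against exhaustive enumeration;
identity stability uses a clean 50-frame, 10-cell sequence.  The
dropout-degraded recall on these synthetic runs (raw ≈ 70%, tracked ≈
92%) is a property of the chosen simulation conditions; only the
*direction and robustness* of the improvement (10/10 seeds) is the
claim.

## Known limitations

- The toy backbone is a pipeline-verification device; real
  re-identification requires the pretrained-backbone adapter.
- Coasted boxes extrapolate the constant-velocity belief; during sharp
  turns they drift, which is why `max_coast` is small.
- The evaluation's greedy matcher is not globally optimal per frame
  (Hungarian matching would be); greedy-by-IoU is the common
  convention for detection scoring and differs only on contrived ties.
- Division handling is purely observational (class flip + new tracks);
  no lineage tree is produced.
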