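# cytotrack

Multi-object cell tracking for time-lapse microscopy.

Per-frame detectors (e.g. a YOLO model run on each microscopy frame)
routinely drop cells for a frame or two — contrast dips, partial
occlusion, a division changing the cell's appearance — leaving holes in
any downstream analysis of migration, proliferation or mitosis.
`cytotrack` links detections across frames into persistent cell
identities and *fills those gaps*: while a cell's detection is missing,
its track coasts on the motion model's prediction and still emits a box,
so the recovered trajectories are continuous.  It is aimed at
quantitative microscopy users who already have detections (or want to
prototype against the bundled simulator) and need trajectories, recall
accounting and identity statistics.

## Method

Each track carries an 8-D state over the bounding box and its
per-frame velocities,

```
x = (cx, cy, a, h, v_cx, v_cy, v_a, v_h),    z = (cx, cy, a, h)
```

propagated by an unscented Kalman filter (UKF) under a constant-velocity
model `x' = F x`, `z = H x` with `F = [[I4, Δt·I4], [0, I4]]`,
`H = [I4 | 0]` and isotropic covariances `P0 = 500·I8`, `Q = 0.1·I8`,
`R = 2·I4`.  The unscented transform (Merwe scaling, α = 1e-3, β = 2,
κ = 0) makes the filter ready for non-linear plug-in dynamics; on the
shipped linear model it provably coincides with the ordinary Kalman
filter, which the test suite uses as an independent oracle.

Appearance is a multi-scale embedding: a backbone produces three feature
maps at decreasing resolution, each is globally average-pooled per
channel (`e_i = mean_{u,v} F_i(u,v,:)`), the pooled vectors are
concatenated and L2-normalized (`ê = [e1;e2;e3] / ‖[e1;e2;e3]‖₂`), and
embeddings are compared by cosine distance `d_cos = 1 − ê_i·ê_j`.

Tracks and detections are associated by minimizing the blended cost

```
C[i,j] = λ·d²_motion(i,j) + (1−λ)·d_cos(i,j)
```

where `d²_motion` is the squared Mahalanobis distance under the track's
predicted measurement distribution, gated at the 95% χ² quantile with
4 df (≈ 9.4877).  The one-to-one assignment is solved with the Hungarian
algorithm inside an age-prioritized matching cascade: tracks seen most
recently get first claim on detections, which keeps identities stable
through occlusions.  Unmatched detections start tentative tracks
(confirmed after `n_init` hits); confirmed tracks survive `max_age`
missed frames and coast their predicted box for up to `max_coast` frames.

Evaluation uses metrics suited to *incompletely annotated* ground truth:
**Modified Recall** `= 100·ΣTP / Σ(TP+FN)` (extra predictions are never
penalized) and **Average IoU** `= 100·Σ IoU_i / N` over matched pairs,
plus an identity-switch counter.

## Worked example

Simulate a degraded detector on synthetic cell motion, track it, and
compare raw detections against the tracker's gap-filled output:

```
$ cytotrack ablate --seed 2 --frames 60 --cells 10 --dropout 0.3
configuration        ModifiedRecall  AverageIoU
raw detections                68.17       92.47
tracked (gap-fill)            88.33       90.95
recall gain                   20.17
```

With 30% of detections randomly dropped, the raw stream recovers 68.17%
of the annotated boxes; the tracker's coasted UKF predictions push that
to 88.33% — a +20-point recall gain — at a modest localization cost
(predicted boxes are slightly less tight than detected ones, hence the
~1.5-point Average IoU dip).

The same pieces are available as separate commands:

```
$ cytotrack simulate --seed 7 --frames 40 --cells-min 8 --cells-max 8 \
    --dropout 0.25 --out-dir demo
simulated 40 frames, 320 GT boxes, 0 divisions -> demo
$ cytotrack track --detections demo/det.txt --out demo/results.txt
$ cytotrack evaluate --gt demo/gt.txt --results demo/results.txt
all: ModifiedRecall=91.88% AverageIoU=89.71% IDswitches=1
```

Files are MOT-challenge CSV (`frame,id,x,y,w,h,conf,class,visibility`);
YOLO-style normalized per-frame files are also supported.  The library
API mirrors the CLI — see `cytotrack.run_sequence`,
`cytotrack.Tracker`, `cytotrack.simulate`, `cytotrack.evaluate_sequences`.

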