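"""Track lifecycle and the per-frame tracking loop.

Each frame the tracker (1) advances every track with a UKF prediction,
(2) associates confirmed tracks to detections through the age-prioritized
matching cascade, (3) gives tentative tracks and just-missed confirmed
tracks a second chance on box overlap, (4) folds matched detections into
the track states and appearance galleries, (5) retires tracks that have
been missing too long, and (6) starts tentative tracks from leftover
detections, confirming them after ``n_init`` consecutive hits.

The tracker's purpose in a microscopy pipeline is *gap-filling*: when the
detector transiently drops a cell, the track coasts on its UKF prediction
and its box is still emitted (flagged ``source="predicted"``), so downstream
analyses see a continuous trajectory instead of a hole.  Coasting is
bounded (``max_coast`` frames) so a genuinely vanished cell does not leave
a phantom box behind.

Division events are not modeled as lineage: a daughter cell simply starts
a new track, and a track's class is that of its most recent matched
detection (mitosis legitimately flips Cell <-> Division, so association is
class-agnostic).
"""

from __future__ import annotations

import enum
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import association as assoc
from .geometry import BoundingBox, ClassLabel, box_to_measurement, measurement_to_box
from .motion import (
    MotionModel,
    TrackState,
    UKFParams,
    initiate,
    make_motion_model,
    predict,
    update,
)

__all__ = [
    "TrackStatus",
    "BoxSource",
    "TrackerConfig",
    "Track",
    "FrameResult",
    "Tracker",
    "run_sequence",
]


class TrackStatus(enum.Enum):
    TENTATIVE = "tentative"
    CONFIRMED = "confirmed"
    DELETED = "deleted"


class BoxSource(enum.Enum):
    DETECTED = "detected"
    PREDICTED = "predicted"


@dataclass(frozen=True)
class TrackerConfig:
    """Tunable tracker behavior.

    Parameters
    ----------
    lambda_weight : float
        Motion-vs-appearance blend in the association cost (1 = motion only).
    n_init : int
        Consecutive hits required before a tentative track is confirmed.
    max_age : int
        Frames a confirmed track may go unmatched before deletion.
    max_coast : int
        Frames for which an unmatched confirmed track still emits its
        UKF-predicted box.
    gallery_size : int
        Embeddings retained per track, oldest evicted first.
    gate_threshold : float
        Squared-Mahalanobis motion gate (default: 95% chi-square, df=4).
    iou_threshold : float
        Minimum overlap for the IoU fallback stage.
    """

    lambda_weight: float = 0.5
    n_init: int = 3
    max_age: int = 30
    max_coast: int = 5
    gallery_size: int = 100
    gate_threshold: float = assoc.CHI2_GATE_95_DF4
    iou_threshold: float = 0.3


@dataclass
class Track:
    """A persistent identity: motion state, lifecycle counters, gallery."""

    track_id: int
    state: TrackState
    class_label: ClassLabel
    status: TrackStatus = TrackStatus.TENTATIVE
    hits: int = 1
    time_since_update: int = 0
    gallery: deque = field(default_factory=lambda: deque(maxlen=100))
    last_box: BoundingBox | None = None
    last_box_source: BoxSource = BoxSource.DETECTED

    def predicted_box(self) -> BoundingBox:
        """The box implied by the current (predicted) state mean."""
        return measurement_to_box(
            self.state.measurement_mean(), class_label=self.class_label
        )


@dataclass
class FrameResult:
    """Per-frame tracker output: one row per emitted confirmed track."""

    frame_index: int
    outputs: list[tuple[int, BoundingBox, ClassLabel, BoxSource]] = field(
        default_factory=list
    )


class Tracker:
    """Online multi-object tracker over a stream of per-frame detections."""

    def __init__(
        self,
        config: TrackerConfig = TrackerConfig(),
        model: MotionModel | None = None,
        ukf_params: UKFParams = UKFParams(),
    ):
        self.config = config
        self.model = model if model is not None else make_motion_model()
        self.ukf_params = ukf_params
        self.tracks: list[Track] = []
        self._next_id = 1
        self._last_frame: int | None = None

    def _new_track(self, det: BoundingBox, emb: np.ndarray | None) -> Track:
        t = Track(
            track_id=self._next_id,
            state=initiate(box_to_measurement(det), self.model),
            class_label=det.class_label,
            gallery=deque(maxlen=self.config.gallery_size),
            last_box=det,
        )
        if emb is not None:
            t.gallery.append(np.asarray(emb, float))
        self._next_id += 1
        return t

    def step(
        self,
        frame_index: int,
        detections: Sequence[BoundingBox],
        embeddings: Sequence[np.ndarray] | None = None,
    ) -> FrameResult:
        """Process one frame; returns the emitted (id, box, class, source) rows."""
        if embeddings is not None and len(embeddings) != len(detections):
            raise ValueError(
                f"{len(embeddings)} embeddings for {len(detections)} detections"
            )
        if self._last_frame is not None and frame_index <= self._last_frame:
            raise ValueError(
                f"frames must be strictly increasing, got {frame_index} after "
                f"{self._last_frame}"
            )
        self._last_frame = frame_index
        cfg = self.config

        # (1) Predict every track; a predicted-but-unmatched track ages by one.
        for t in self.tracks:
            t.state = predict(t.state, self.model, self.ukf_params)
            t.time_since_update += 1

        # (2) Matching cascade over confirmed tracks.
        confirmed_idx = [
            i for i, t in enumerate(self.tracks) if t.status is TrackStatus.CONFIRMED
        ]
        confirmed = [self.tracks[i] for i in confirmed_idx]
        cascade = assoc.matching_cascade(
            confirmed,
            detections,
            embeddings,
            cfg.max_age,
            cfg.lambda_weight,
            self.model,
            self.ukf_params,
            cfg.gate_threshold,
        )
        matches: list[tuple[int, int]] = [
            (confirmed_idx[r], c) for r, c in cascade.matches
        ]

        # (3) IoU fallback: tentative tracks plus confirmed ones missed only
        # in this frame (their motion gate is still trustworthy).
        fallback_idx = [
            i for i, t in enumerate(self.tracks) if t.status is TrackStatus.TENTATIVE
        ] + [
            confirmed_idx[r]
            for r in cascade.unmatched_tracks
            if self.tracks[confirmed_idx[r]].time_since_update == 1
        ]
        remaining_dets = list(cascade.unmatched_detections)
        if fallback_idx and remaining_dets:
            sub = assoc.iou_match(
                [self.tracks[i] for i in fallback_idx],
                [detections[j] for j in remaining_dets],
                cfg.iou_threshold,
            )
            for r, c in sub.matches:
                matches.append((fallback_idx[r], remaining_dets[c]))
            remaining_dets = [remaining_dets[c] for c in sub.unmatched_detections]

        # (4) Fold matched detections into their tracks.
        matched_track_idx = set()
        for ti, dj in matches:
            t = self.tracks[ti]
            det = detections[dj]
            t.state = update(
                t.state, box_to_measurement(det), self.model, self.ukf_params
            )
            if embeddings is not None:
                t.gallery.append(np.asarray(embeddings[dj], float))
            t.hits += 1
            t.time_since_update = 0
            t.class_label = det.class_label
            t.last_box = det
            t.last_box_source = BoxSource.DETECTED
            matched_track_idx.add(ti)

        # (5) Lifecycle: missed tentatives die immediately; confirmed tracks
        # die after max_age missed frames; tentatives confirm at n_init hits.
        for i, t in enumerate(self.tracks):
            if i in matched_track_idx:
                if t.status is TrackStatus.TENTATIVE and t.hits >= cfg.n_init:
                    t.status = TrackStatus.CONFIRMED
                continue
            if t.status is TrackStatus.TENTATIVE:
                t.status = TrackStatus.DELETED
            elif t.time_since_update > cfg.max_age:
                t.status = TrackStatus.DELETED

        # (6) Leftover detections seed new tentative tracks.
        for dj in remaining_dets:
            emb = None if embeddings is None else embeddings[dj]
            t = self._new_track(detections[dj], emb)
            if cfg.n_init <= 1:
                t.status = TrackStatus.CONFIRMED
            self.tracks.append(t)

        self.tracks = [t for t in self.tracks if t.status is not TrackStatus.DELETED]

        # (7) Emit confirmed tracks: matched ones with their detection box,
        # recently missed ones with the coasted UKF prediction.
        result = FrameResult(frame_index=frame_index)
        for t in self.tracks:
            if t.status is not TrackStatus.CONFIRMED:
                continue
            if t.time_since_update == 0:
                result.outputs.append(
                    (t.track_id, t.last_box, t.class_label, BoxSource.DETECTED)
                )
            elif t.time_since_update <= cfg.max_coast:
                box = t.predicted_box()
                t.last_box = box
                t.last_box_source = BoxSource.PREDICTED
                result.outputs.append(
                    (t.track_id, box, t.class_label, BoxSource.PREDICTED)
                )
        return result


def run_sequence(
    detection_stream: dict[int, list[BoundingBox]]
    | Iterable[tuple[int, list[BoundingBox]]],
    frames: dict[int, np.ndarray] | None = None,
    backbone=None,
    config: TrackerConfig = TrackerConfig(),
    model: MotionModel | None = None,
    ukf_params: UKFParams = UKFParams(),
) -> list[FrameResult]:
    """Fold the tracker over an ordered detection stream.

    ``detection_stream`` maps frame index to its detections (dict or
    already-ordered iterable of pairs).  If ``frames`` and ``backbone`` are
    given, appearance embeddings are computed per detection crop; otherwise
    association is motion-only.  Deterministic given identical inputs.
    """
    from .appearance import embed_detections  # local: optional heavy path

    if isinstance(detection_stream, dict):
        items = sorted(detection_stream.items())
    else:
        items = list(detection_stream)
        if any(b[0] <= a[0] for a, b in zip(items, items[1:])):
            raise ValueError("detection stream frames must be strictly increasing")
    tracker = Tracker(config=config, model=model, ukf_params=ukf_params)
    results = []
    for frame_index, dets in items:
        emb = None
        if frames is not None and backbone is not None and dets:
            emb = embed_detections(frames[frame_index], dets, backbone)
        results.append(tracker.step(frame_index, dets, emb))
    return results
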