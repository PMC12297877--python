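"""Readers and writers for the tracking file formats.

Two text dialects are supported:

* **MOT-challenge CSV** — one record per line,
  ``frame,id,x,y,w,h,confidence,class,visibility`` with 1-based frame
  numbers, top-left box convention and ``id = -1`` for raw detections.
  Class map: ``{1: Cell, 2: Division}``.  Tracker results reuse the
  visibility column as the box-source flag (1 = detected, 0 = coasted
  UKF prediction).
* **YOLO per-frame text** — ``class cx cy w h [confidence]`` with
  center-format coordinates normalized to the frame size.  Class map:
  ``{0: Cell, 1: Division}``.

Writers are deterministic: records are sorted by (frame, id), pixels are
printed with 2 decimals and confidences with 6, so writing the same data
twice is byte-identical and a write/read round-trip is lossless at that
precision.  A flat ``key = value`` config-file parser backs the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .geometry import BoundingBox, ClassLabel
from .tracker import BoxSource, FrameResult

__all__ = [
    "MotRecord",
    "read_mot",
    "write_mot",
    "read_yolo_frame",
    "write_yolo_frame",
    "mot_to_detections",
    "mot_to_stream",
    "gt_to_mot",
    "detections_to_mot",
    "results_to_mot",
    "results_to_stream",
    "read_config",
    "MotParseError",
]

MOT_CLASS_TO_LABEL = {1: ClassLabel.CELL, 2: ClassLabel.DIVISION}
MOT_LABEL_TO_CLASS = {v: k for k, v in MOT_CLASS_TO_LABEL.items()}
YOLO_CLASS_TO_LABEL = {0: ClassLabel.CELL, 1: ClassLabel.DIVISION}
YOLO_LABEL_TO_CLASS = {v: k for k, v in YOLO_CLASS_TO_LABEL.items()}


class MotParseError(ValueError):
    """A malformed line in a MOT or YOLO file (reported with line number)."""


@dataclass(frozen=True)
class MotRecord:
    """One MOT-challenge CSV row."""

    frame: int  # 1-based
    id: int  # -1 for raw detections
    x: float
    y: float
    w: float
    h: float
    confidence: float = 1.0
    class_id: int = 1
    visibility: float = 1.0

    def __post_init__(self) -> None:
        if self.frame < 1:
            raise ValueError(f"MOT frames are 1-based, got {self.frame}")
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"non-positive box size w={self.w}, h={self.h}")

    def to_box(self) -> BoundingBox:
        return BoundingBox(
            x=self.x,
            y=self.y,
            w=self.w,
            h=self.h,
            class_label=MOT_CLASS_TO_LABEL.get(self.class_id, ClassLabel.CELL),
            confidence=min(max(self.confidence, 0.0), 1.0),
        )


def read_mot(path: str | Path) -> list[MotRecord]:
    """Parse a MOT CSV file; raises :class:`MotParseError` with line numbers."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if len(parts) != 9:
                raise MotParseError(
                    f"{path}:{lineno}: expected 9 comma-separated fields, "
                    f"got {len(parts)}"
                )
            try:
                records.append(
                    MotRecord(
                        frame=int(parts[0]),
                        id=int(parts[1]),
                        x=float(parts[2]),
                        y=float(parts[3]),
                        w=float(parts[4]),
                        h=float(parts[5]),
                        confidence=float(parts[6]),
                        class_id=int(parts[7]),
                        visibility=float(parts[8]),
                    )
                )
            except ValueError as exc:
                raise MotParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_mot(path: str | Path, records: list[MotRecord]) -> None:
    """Write records sorted by (frame, id) with fixed decimal formatting."""
    with open(path, "w") as fh:
        for r in sorted(records, key=lambda r: (r.frame, r.id)):
            fh.write(
                f"{r.frame},{r.id},{r.x:.2f},{r.y:.2f},{r.w:.2f},{r.h:.2f},"
                f"{r.confidence:.6f},{r.class_id},{r.visibility:.2f}\n"
            )


def read_yolo_frame(
    path: str | Path, frame_width: int, frame_height: int
) -> list[BoundingBox]:
    """Denormalize a YOLO per-frame text file into top-left boxes."""
    if frame_width <= 0 or frame_height <= 0:
        raise ValueError("frame dimensions must be positive")
    boxes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (5, 6):
                raise MotParseError(
                    f"{path}:{lineno}: expected 5 or 6 fields, got {len(parts)}"
                )
            try:
                class_id = int(parts[0])
                vals = [float(v) for v in parts[1:5]]
                conf = float(parts[5]) if len(parts) == 6 else 1.0
            except ValueError as exc:
                raise MotParseError(f"{path}:{lineno}: {exc}") from exc
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise MotParseError(
                    f"{path}:{lineno}: normalized values outside [0, 1]: {vals}"
                )
            cxn, cyn, wn, hn = vals
            w = wn * frame_width
            h = hn * frame_height
            boxes.append(
                BoundingBox(
                    x=cxn * frame_width - w / 2.0,
                    y=cyn * frame_height - h / 2.0,
                    w=w,
                    h=h,
                    class_label=YOLO_CLASS_TO_LABEL.get(class_id, ClassLabel.CELL),
                    confidence=conf,
                )
            )
    return boxes


def write_yolo_frame(
    path: str | Path,
    boxes: list[BoundingBox],
    frame_width: int,
    frame_height: int,
) -> None:
    with open(path, "w") as fh:
        for b in boxes:
            cxn = (b.x + b.w / 2.0) / frame_width
            cyn = (b.y + b.h / 2.0) / frame_height
            fh.write(
                f"{YOLO_LABEL_TO_CLASS[b.class_label]} "
                f"{cxn:.9f} {cyn:.9f} {b.w / frame_width:.9f} "
                f"{b.h / frame_height:.9f} {b.confidence:.6f}\n"
            )


# ---------------------------------------------------------------------------
# Conversions between file records and in-memory streams.

def mot_to_detections(records: list[MotRecord]) -> dict[int, list[BoundingBox]]:
    """Group detection records into a 0-based ``frame -> boxes`` stream."""
    stream: dict[int, list[BoundingBox]] = {}
    for r in records:
        stream.setdefault(r.frame - 1, []).append(r.to_box())
    return stream


def mot_to_stream(
    records: list[MotRecord],
) -> dict[int, list[tuple[int, BoundingBox]]]:
    """Group GT/result records into a 0-based ``frame -> [(id, box)]`` stream."""
    stream: dict[int, list[tuple[int, BoundingBox]]] = {}
    for r in records:
        stream.setdefault(r.frame - 1, []).append((r.id, r.to_box()))
    return stream


def gt_to_mot(gt) -> list[MotRecord]:
    """Serialize a simulated ground-truth sequence (visibility 1)."""
    records = []
    for t in sorted(gt.frames):
        for cell_id, box, label in gt.frames[t]:
            records.append(
                MotRecord(
                    frame=t + 1,
                    id=cell_id,
                    x=round(box.x, 2),
                    y=round(box.y, 2),
                    w=round(box.w, 2),
                    h=round(box.h, 2),
                    confidence=1.0,
                    class_id=MOT_LABEL_TO_CLASS[label],
                )
            )
    return records


def detections_to_mot(stream: dict[int, list[BoundingBox]]) -> list[MotRecord]:
    """Serialize a detection stream with the conventional ``id = -1``."""
    records = []
    for t in sorted(stream):
        for box in stream[t]:
            records.append(
                MotRecord(
                    frame=t + 1,
                    id=-1,
                    x=round(box.x, 2),
                    y=round(box.y, 2),
                    w=round(box.w, 2),
                    h=round(box.h, 2),
                    confidence=round(box.confidence, 6),
                    class_id=MOT_LABEL_TO_CLASS[box.class_label],
                )
            )
    return records


def results_to_mot(
    results: list[FrameResult], include_predicted: bool = True
) -> list[MotRecord]:
    """Serialize tracker output; visibility encodes the box source."""
    records = []
    for fr in results:
        for track_id, box, label, source in fr.outputs:
            if source is BoxSource.PREDICTED and not include_predicted:
                continue
            records.append(
                MotRecord(
                    frame=fr.frame_index + 1,
                    id=track_id,
                    x=round(box.x, 2),
                    y=round(box.y, 2),
                    w=round(box.w, 2),
                    h=round(box.h, 2),
                    confidence=round(box.confidence, 6),
                    class_id=MOT_LABEL_TO_CLASS[label],
                    visibility=1.0 if source is BoxSource.DETECTED else 0.0,
                )
            )
    return records


def results_to_stream(
    results: list[FrameResult], include_predicted: bool = True
) -> dict[int, list[tuple[int, BoundingBox]]]:
    """In-memory ``frame -> [(track_id, box)]`` view of tracker output."""
    stream: dict[int, list[tuple[int, BoundingBox]]] = {}
    for fr in results:
        rows = []
        for track_id, box, _, source in fr.outputs:
            if source is BoxSource.PREDICTED and not include_predicted:
                continue
            rows.append((track_id, box))
        stream[fr.frame_index] = rows
    return stream


def read_config(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` config file; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise MotParseError(
                    f"{path}:{lineno}: expected 'key = value', got {line!r}"
                )
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out
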