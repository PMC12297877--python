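"""Bounding boxes, the tracker's measurement space, and IoU.

Boxes live in 0-based pixel coordinates with the origin at the top-left
corner and are treated as closed real-valued rectangles ``[x, x+w] x
[y, y+h]``; IoU uses real-valued areas, so no pixel discretization is
involved.  The tracker's measurement vector holds the box center, aspect
ratio and height ``(cx, cy, a, h)`` — the observable part of the motion
state.  Class labels (Cell vs. Division) ride along untouched; geometry
itself is class-agnostic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ClassLabel",
    "BoundingBox",
    "Measurement",
    "box_to_measurement",
    "measurement_to_box",
    "iou",
    "iou_matrix",
    "InvalidBoxError",
    "InvalidMeasurementError",
]


class InvalidBoxError(ValueError):
    """A bounding box with non-positive width or height."""


class InvalidMeasurementError(ValueError):
    """A measurement with non-positive aspect ratio or height."""


class ClassLabel(enum.Enum):
    """Object classes: migrating cells vs. cells in pro/metaphase."""

    CELL = "Cell"
    DIVISION = "Division"


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in top-left/width/height pixel convention.

    Parameters
    ----------
    x, y : float
        Top-left corner in pixels.
    w, h : float
        Width and height in pixels; must be positive.
    class_label : ClassLabel
        Detector class; Division marks a cell in pro/metaphase.
    confidence : float
        Detector confidence in [0, 1].
    """

    x: float
    y: float
    w: float
    h: float
    class_label: ClassLabel = ClassLabel.CELL
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise InvalidBoxError(
                f"box width/height must be positive, got w={self.w}, h={self.h}"
            )
        if not (0.0 <= self.confidence <= 1.0):
            raise InvalidBoxError(
                f"confidence must lie in [0, 1], got {self.confidence}"
            )
        if not all(np.isfinite([self.x, self.y, self.w, self.h])):
            raise InvalidBoxError("box coordinates must be finite")

    @property
    def area(self) -> float:
        return self.w * self.h

    def to_xyxy(self) -> tuple[float, float, float, float]:
        return (self.x, self.y, self.x + self.w, self.y + self.h)

    def with_confidence(self, confidence: float) -> "BoundingBox":
        return replace(self, confidence=confidence)


@dataclass(frozen=True)
class Measurement:
    """Observable state ``(cx, cy, a, h)``: box center, aspect ratio, height."""

    cx: float
    cy: float
    a: float
    h: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.h > 0):
            raise InvalidMeasurementError(
                f"aspect ratio and height must be positive, got a={self.a}, h={self.h}"
            )

    def to_array(self) -> np.ndarray:
        return np.array([self.cx, self.cy, self.a, self.h], dtype=float)

    @classmethod
    def from_array(cls, z: np.ndarray) -> "Measurement":
        cx, cy, a, h = (float(v) for v in np.asarray(z, dtype=float))
        return cls(cx, cy, a, h)


def box_to_measurement(b: BoundingBox) -> Measurement:
    """Map a detector box to the measurement vector (center, aspect, height)."""
    return Measurement(cx=b.x + b.w / 2.0, cy=b.y + b.h / 2.0, a=b.w / b.h, h=b.h)


def measurement_to_box(
    z: Measurement,
    class_label: ClassLabel = ClassLabel.CELL,
    confidence: float = 1.0,
) -> BoundingBox:
    """Inverse of :func:`box_to_measurement`; class/confidence are supplied."""
    w = z.a * z.h
    return BoundingBox(
        x=z.cx - w / 2.0,
        y=z.cy - z.h / 2.0,
        w=w,
        h=z.h,
        class_label=class_label,
        confidence=confidence,
    )


def iou(b1: BoundingBox, b2: BoundingBox) -> float:
    """Intersection-over-union of two boxes on real-valued areas.

    Symmetric, 1 for identical boxes, 0 for disjoint ones.
    """
    ax0, ay0, ax1, ay1 = b1.to_xyxy()
    bx0, by0, bx1, by1 = b2.to_xyxy()
    ix = min(ax1, bx1) - max(ax0, bx0)
    iy = min(ay1, by1) - max(ay0, by0)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    # Areas from the same corner differences as the intersection, so that
    # identical boxes give exactly 1.0.
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union


def iou_matrix(
    boxes_a: list[BoundingBox], boxes_b: list[BoundingBox]
) -> np.ndarray:
    """Pairwise IoU, shape ``(len(boxes_a), len(boxes_b))``.

    Vectorized for the association and evaluation hot paths.
    """
    if not boxes_a or not boxes_b:
        return np.zeros((len(boxes_a), len(boxes_b)))
    A = np.array([b.to_xyxy() for b in boxes_a])  # (N, 4)
    B = np.array([b.to_xyxy() for b in boxes_b])  # (M, 4)
    ix = np.minimum(A[:, None, 2], B[None, :, 2]) - np.maximum(
        A[:, None, 0], B[None, :, 0]
    )
    iy = np.minimum(A[:, None, 3], B[None, :, 3]) - np.maximum(
        A[:, None, 1], B[None, :, 1]
    )
    inter = np.clip(ix, 0.0, None) * np.clip(iy, 0.0, None)
    area_a = (A[:, 2] - A[:, 0]) * (A[:, 3] - A[:, 1])
    area_b = (B[:, 2] - B[:, 0]) * (B[:, 3] - B[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return inter / union
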