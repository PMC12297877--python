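"""Synthetic time-lapse cell-motion generator.

Emulates the statistical structure of grayscale adherent-culture
microscopy sequences: 10–22 moderately sparse objects per 1600x1200
frame, two classes (Cell, and a rarer Division class that is larger and
rounder), division events that split a parent into two daughter cells,
and a degradation stage that models detector dropout and box jitter.

Cells move on a *heading-noise random walk* — each frame the heading gets
Gaussian turn noise and the cell advances at its own constant speed.
This motion is deliberately non-linear relative to the tracker's
constant-velocity model, so tracking tests exercise the filter on
mismatched dynamics rather than on its own assumptions.

Rendering is optional: each cell is drawn as an anisotropic Gaussian blob
modulated by a per-cell speckle texture (its "appearance signature") on a
noisy gray background, so appearance embeddings can distinguish cells.
Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import resize

from .geometry import BoundingBox, ClassLabel

__all__ = [
    "SimConfig",
    "GroundTruthSequence",
    "simulate",
    "degrade",
    "render",
    "render_frame",
    "invert_intensity",
    "SimConfigError",
]


class SimConfigError(ValueError):
    """An invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Defaults describe a moderately sparse adherent culture on a
    1600x1200 sensor: 10–22 cells of ~40 px height moving 1–4 px/frame
    with heading noise, rare division events that inflate the box 1.4x
    and round the aspect ratio before splitting into two daughters.
    """

    frame_count: int = 100
    frame_size: tuple[int, int] = (1600, 1200)  # (width, height)
    cells_per_frame_range: tuple[int, int] = (10, 22)
    division_rate: float = 0.005  # per cell per frame
    division_duration: int = 6  # frames spent in the Division class
    division_inflate: float = 1.4
    speed_range: tuple[float, float] = (1.0, 4.0)  # px/frame
    turn_sigma: float = 0.3  # rad/frame heading noise
    cell_h_mean: float = 40.0
    cell_h_sigma: float = 8.0
    cell_aspect_mean: float = 1.2
    cell_aspect_sigma: float = 0.2
    min_separation: float = 80.0  # px between initial cell centers
    dropout_p: float = 0.1  # detector miss probability (degrade stage)
    jitter_sigma: float = 1.0  # box-noise sigma in px (degrade stage)
    background_level: float = 100.0
    background_noise: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_count < 1:
            raise SimConfigError("frame_count must be >= 1")
        for p in (self.division_rate, self.dropout_p):
            if not 0.0 <= p <= 1.0:
                raise SimConfigError(f"probability {p} outside [0, 1]")
        lo, hi = self.cells_per_frame_range
        if not (1 <= lo <= hi):
            raise SimConfigError("cells_per_frame_range must be 1 <= lo <= hi")
        if self.jitter_sigma < 0 or self.turn_sigma < 0:
            raise SimConfigError("noise sigmas must be non-negative")


@dataclass
class GroundTruthSequence:
    """Per-frame annotated objects plus the division lineage.

    ``frames[t]`` is a list of ``(cell_id, box, class_label)`` triples;
    ``lineage`` maps a parent id to its two daughters' ids.
    """

    frames: dict[int, list[tuple[int, BoundingBox, ClassLabel]]]
    lineage: dict[int, tuple[int, int]] = field(default_factory=dict)
    config: SimConfig | None = None

    def as_stream(self) -> dict[int, list[tuple[int, BoundingBox]]]:
        """The ``frame -> [(id, box)]`` view used by the evaluation module."""
        return {
            t: [(cid, box) for cid, box, _ in objs]
            for t, objs in self.frames.items()
        }

    def boxes(self) -> dict[int, list[BoundingBox]]:
        return {t: [box for _, box, _ in objs] for t, objs in self.frames.items()}


@dataclass
class _Cell:
    cell_id: int
    x: float
    y: float
    heading: float
    speed: float
    h: float
    aspect: float
    dividing: bool = False
    division_left: int = 0


def _cell_box(c: _Cell, config: SimConfig) -> tuple[BoundingBox, ClassLabel]:
    if c.dividing:
        h = c.h * config.division_inflate
        a = 1.0  # rounder during pro/metaphase
        label = ClassLabel.DIVISION
    else:
        h, a, label = c.h, c.aspect, ClassLabel.CELL
    w = a * h
    W, H = config.frame_size
    # Clip to the frame; centers stay inside so the intersection is nonempty.
    x0 = max(c.x - w / 2.0, 0.0)
    y0 = max(c.y - h / 2.0, 0.0)
    x1 = min(c.x + w / 2.0, float(W))
    y1 = min(c.y + h / 2.0, float(H))
    return (
        BoundingBox(x=x0, y=y0, w=x1 - x0, h=y1 - y0, class_label=label),
        label,
    )


def _spawn(rng: np.random.Generator, cell_id: int, config: SimConfig,
           x: float | None = None, y: float | None = None,
           h: float | None = None) -> _Cell:
    W, H = config.frame_size
    margin = config.cell_h_mean
    return _Cell(
        cell_id=cell_id,
        x=float(rng.uniform(margin, W - margin)) if x is None else x,
        y=float(rng.uniform(margin, H - margin)) if y is None else y,
        heading=float(rng.uniform(0.0, 2.0 * np.pi)),
        speed=float(rng.uniform(*config.speed_range)),
        h=float(
            np.clip(rng.normal(config.cell_h_mean, config.cell_h_sigma), 10.0, None)
        ) if h is None else h,
        aspect=float(
            np.clip(
                rng.normal(config.cell_aspect_mean, config.cell_aspect_sigma),
                0.5,
                2.5,
            )
        ),
    )


def simulate(config: SimConfig) -> GroundTruthSequence:
    """Generate a ground-truth sequence under the configured dynamics.

    Deterministic given ``config.seed``.  With ``division_rate = 0`` the
    per-frame object count is constant and equal to the initial draw from
    ``cells_per_frame_range``.
    """
    rng = np.random.default_rng(config.seed)
    W, H = config.frame_size
    lo, hi = config.cells_per_frame_range
    n0 = int(rng.integers(lo, hi + 1))
    next_id = 1
    cells: list[_Cell] = []
    for _ in range(n0):
        # Cultures are moderately sparse: resample initial positions that
        # land too close to an existing cell (best effort, bounded tries).
        for _attempt in range(50):
            c = _spawn(rng, next_id, config)
            if all(
                np.hypot(c.x - o.x, c.y - o.y) >= config.min_separation
                for o in cells
            ):
                break
        cells.append(c)
        next_id += 1

    frames: dict[int, list[tuple[int, BoundingBox, ClassLabel]]] = {}
    lineage: dict[int, tuple[int, int]] = {}

    for t in range(config.frame_count):
        frames[t] = [
            (c.cell_id, *_cell_box(c, config)) for c in cells
        ]
        if t == config.frame_count - 1:
            break  # no evolution past the last recorded frame
        # Evolve to the next frame.
        new_cells: list[_Cell] = []
        for c in cells:
            if c.dividing:
                c.division_left -= 1
                if c.division_left <= 0:
                    # Split: parent disappears, two daughters appear.
                    angle = c.heading + np.pi / 2.0
                    off = c.h * 0.45
                    daughters = []
                    for s in (+1.0, -1.0):
                        d = _spawn(
                            rng,
                            next_id,
                            config,
                            x=float(np.clip(c.x + s * off * np.cos(angle), 1.0, W - 1.0)),
                            y=float(np.clip(c.y + s * off * np.sin(angle), 1.0, H - 1.0)),
                            h=max(c.h * 0.8, 10.0),
                        )
                        daughters.append(d)
                        next_id += 1
                    lineage[c.cell_id] = (daughters[0].cell_id, daughters[1].cell_id)
                    new_cells.extend(daughters)
                    continue
            else:
                if rng.random() < config.division_rate:
                    c.dividing = True
                    c.division_left = config.division_duration
            c.heading += float(rng.normal(0.0, config.turn_sigma))
            c.x += c.speed * np.cos(c.heading)
            c.y += c.speed * np.sin(c.heading)
            # Reflect at the walls so cells never leave the field of view.
            if c.x < 1.0 or c.x > W - 1.0:
                c.heading = np.pi - c.heading
                c.x = float(np.clip(c.x, 1.0, W - 1.0))
            if c.y < 1.0 or c.y > H - 1.0:
                c.heading = -c.heading
                c.y = float(np.clip(c.y, 1.0, H - 1.0))
            new_cells.append(c)
        cells = new_cells

    return GroundTruthSequence(frames=frames, lineage=lineage, config=config)


def degrade(
    gt: GroundTruthSequence,
    dropout_p: float | None = None,
    jitter_sigma: float | None = None,
    seed: int | None = None,
    clutter_rate: float = 0.0,
) -> dict[int, list[BoundingBox]]:
    """Turn perfect annotations into an imperfect detection stream.

    Each box is dropped independently with probability ``dropout_p``;
    survivors get Gaussian noise on center and size and a confidence drawn
    uniformly from [0.5, 1].  ``clutter_rate`` (expected false positives
    per frame, default 0) optionally adds spurious boxes for stress tests.
    Defaults come from the sequence's own config.
    """
    config = gt.config if gt.config is not None else SimConfig()
    if dropout_p is None:
        dropout_p = config.dropout_p
    if jitter_sigma is None:
        jitter_sigma = config.jitter_sigma
    if seed is None:
        seed = config.seed + 1
    rng = np.random.default_rng(seed)
    W, H = config.frame_size
    stream: dict[int, list[BoundingBox]] = {}
    for t in sorted(gt.frames):
        dets: list[BoundingBox] = []
        for _, box, label in gt.frames[t]:
            if rng.random() < dropout_p:
                continue
            cx = box.x + box.w / 2.0 + rng.normal(0.0, jitter_sigma)
            cy = box.y + box.h / 2.0 + rng.normal(0.0, jitter_sigma)
            w = max(box.w + rng.normal(0.0, jitter_sigma), 2.0)
            h = max(box.h + rng.normal(0.0, jitter_sigma), 2.0)
            dets.append(
                BoundingBox(
                    x=cx - w / 2.0,
                    y=cy - h / 2.0,
                    w=w,
                    h=h,
                    class_label=label,
                    confidence=float(rng.uniform(0.5, 1.0)),
                )
            )
        for _ in range(rng.poisson(clutter_rate)):
            w = float(rng.uniform(15.0, 60.0))
            h = float(rng.uniform(15.0, 60.0))
            dets.append(
                BoundingBox(
                    x=float(rng.uniform(0.0, W - w)),
                    y=float(rng.uniform(0.0, H - h)),
                    w=w,
                    h=h,
                    class_label=ClassLabel.CELL,
                    confidence=float(rng.uniform(0.5, 1.0)),
                )
            )
        stream[t] = dets
    return stream


def _speckle(cell_id: int, base_seed: int, shape: tuple[int, int]) -> np.ndarray:
    """Per-cell multiplicative texture — the cell's appearance signature."""
    rng = np.random.default_rng((base_seed * 1_000_003 + cell_id) % (2**31))
    coarse = rng.uniform(0.6, 1.4, size=(6, 6))
    return resize(coarse, shape, order=1, anti_aliasing=False, preserve_range=True)


def render_frame(
    gt: GroundTruthSequence, frame_index: int, config: SimConfig | None = None
) -> np.ndarray:
    """Render one frame: Gaussian-blob cells on a noisy gray background."""
    config = config if config is not None else (gt.config or SimConfig())
    W, H = config.frame_size
    rng = np.random.default_rng((config.seed * 7_919 + frame_index) % (2**31))
    frame = rng.normal(config.background_level, config.background_noise, (H, W))
    for cell_id, box, label in gt.frames.get(frame_index, []):
        x0, y0 = int(np.floor(box.x)), int(np.floor(box.y))
        x1, y1 = int(np.ceil(box.x + box.w)), int(np.ceil(box.y + box.h))
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, W), min(y1, H)
        if x1 <= x0 or y1 <= y0:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        cx, cy = box.x + box.w / 2.0, box.y + box.h / 2.0
        sx, sy = box.w / 4.0, box.h / 4.0
        blob = np.exp(
            -0.5 * (((xx - cx) / sx) ** 2 + ((yy - cy) / sy) ** 2)
        )
        amp_rng = np.random.default_rng(
            (config.seed * 104_729 + cell_id) % (2**31)
        )
        amp = float(amp_rng.uniform(60.0, 120.0))
        if label is ClassLabel.DIVISION:
            amp *= 1.3  # dividing cells appear brighter
        texture = _speckle(cell_id, config.seed, blob.shape)
        frame[y0:y1, x0:x1] += amp * blob * texture
    return np.clip(frame, 0.0, 255.0).astype(np.uint8)


def render(
    gt: GroundTruthSequence, config: SimConfig | None = None
) -> dict[int, np.ndarray]:
    """Render every frame of the sequence (8-bit grayscale)."""
    return {
        t: render_frame(gt, t, config) for t in sorted(gt.frames)
    }


def invert_intensity(frame: np.ndarray) -> np.ndarray:
    """Grayscale inversion augmentation: ``pixel -> 255 - pixel``."""
    frame = np.asarray(frame)
    if frame.dtype != np.uint8:
        raise ValueError("invert_intensity expects an 8-bit grayscale frame")
    return (255 - frame).astype(np.uint8)
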