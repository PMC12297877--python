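"""Multi-scale appearance embeddings and cosine distance.

A backbone maps a resized image crop to exactly three feature maps at
strictly decreasing spatial resolution (mirroring features tapped from
successive stages of a convolutional network such as ResNet50).  Each map
is globally average-pooled over space into a per-channel vector
``e_i[c] = mean_{u,v} F_i(u, v, c)``; the three pooled vectors are
concatenated and L2-normalized into the final embedding
``e_hat = [e1; e2; e3] / ||[e1; e2; e3]||_2``.  Embeddings are compared by
cosine distance ``1 - (a.b) / (||a|| ||b||)``, which lies in [0, 2].

The backbone is a *contract*, not a dependency: any callable producing
three such maps plugs in.  The default :class:`ToyBackbone` is a
deterministic, training-free stand-in built from seeded random patch
projections — enough to verify the pooling/fusion/distance pipeline and to
separate visually distinct cells, with no pretrained weights involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
from skimage.transform import resize

from .geometry import BoundingBox

__all__ = [
    "FeatureMap",
    "BackboneContract",
    "ToyBackbone",
    "pool_feature_map",
    "fuse_embeddings",
    "cosine_distance",
    "embed_detections",
    "DegenerateEmbeddingError",
    "InvalidCropError",
]


class DegenerateEmbeddingError(ValueError):
    """An all-zero vector where a direction is required."""


class InvalidCropError(ValueError):
    """An empty crop or a box fully outside the frame."""


@dataclass(frozen=True)
class FeatureMap:
    """One backbone stage's output: an ``H x W x C`` activation array."""

    values: np.ndarray
    scale_id: int

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 3 or min(v.shape) < 1:
            raise InvalidCropError(
                f"feature map must be H x W x C with all dims >= 1, got {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("feature map contains non-finite values")


class BackboneContract(Protocol):
    """Callable from a 2-D grayscale crop to three multi-scale feature maps."""

    input_size: int

    def __call__(self, crop: np.ndarray) -> tuple[FeatureMap, FeatureMap, FeatureMap]:
        ...


def pool_feature_map(f: FeatureMap) -> np.ndarray:
    """Global average pooling: spatial mean per channel."""
    return f.values.mean(axis=(0, 1))


def fuse_embeddings(
    e1: np.ndarray, e2: np.ndarray, e3: np.ndarray
) -> np.ndarray:
    """Concatenate pooled vectors in scale order and L2-normalize."""
    e = np.concatenate([np.asarray(e1, float), np.asarray(e2, float), np.asarray(e3, float)])
    norm = np.linalg.norm(e)
    if norm == 0.0:
        raise DegenerateEmbeddingError("all-zero concatenated embedding")
    return e / norm


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    """``1 - cos(angle)`` between two embeddings; symmetric, in [0, 2].

    Norms are divided out explicitly so unnormalized inputs are handled
    correctly, even though fused embeddings are already unit vectors.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise DegenerateEmbeddingError("cosine distance of a zero vector")
    return float(np.clip(1.0 - (a @ b) / (na * nb), 0.0, 2.0))


def cosine_distance_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise cosine distances between rows of ``A`` and rows of ``B``."""
    A = np.atleast_2d(np.asarray(A, float))
    B = np.atleast_2d(np.asarray(B, float))
    na = np.linalg.norm(A, axis=1, keepdims=True)
    nb = np.linalg.norm(B, axis=1, keepdims=True)
    if np.any(na == 0.0) or np.any(nb == 0.0):
        raise DegenerateEmbeddingError("cosine distance of a zero vector")
    return np.clip(1.0 - (A / na) @ (B / nb).T, 0.0, 2.0)


class ToyBackbone:
    """Deterministic training-free backbone for tests and synthetic runs.

    The crop (already resized to ``input_size``) is block-averaged to a
    32x32 working image, then each scale extracts non-overlapping patches
    (2x2, 4x4, 8x8) and projects them through a fixed random matrix drawn
    once from ``seed``, followed by tanh.  Output resolutions are 16x16,
    8x8 and 4x4 — strictly decreasing — with channel counts 8/16/32 by
    default.  Identical crops give bitwise-identical features.
    """

    WORK = 32

    def __init__(
        self,
        channels: tuple[int, int, int] = (8, 16, 32),
        input_size: int = 128,
        seed: int = 0,
    ):
        if input_size % self.WORK != 0:
            raise ValueError(f"input_size must be a multiple of {self.WORK}")
        self.channels = channels
        self.input_size = input_size
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._patch = (2, 4, 8)
        # One fixed affine projection per scale: (patch*patch + 1, C_i); the
        # extra bias row keeps constant (e.g. all-black) crops embeddable.
        self._proj = [
            rng.standard_normal((p * p + 1, c)) / p
            for p, c in zip(self._patch, channels)
        ]

    def __call__(self, crop: np.ndarray) -> tuple[FeatureMap, FeatureMap, FeatureMap]:
        crop = np.asarray(crop, dtype=float)
        if crop.ndim == 3:  # collapse replicated channels
            crop = crop.mean(axis=2)
        if crop.size == 0:
            raise InvalidCropError("empty crop")
        if crop.shape != (self.input_size, self.input_size):
            crop = resize(
                crop, (self.input_size, self.input_size), order=1,
                anti_aliasing=False, preserve_range=True,
            )
        k = self.input_size // self.WORK
        work = crop.reshape(self.WORK, k, self.WORK, k).mean(axis=(1, 3))
        # Per-crop standardization: discards absolute intensity so the
        # embedding encodes texture/shape contrast, not illumination.
        work = (work - work.mean()) / (work.std() + 1e-6)
        maps = []
        for i, (p, proj) in enumerate(zip(self._patch, self._proj)):
            hw = self.WORK // p
            patches = (
                work.reshape(hw, p, hw, p)
                .transpose(0, 2, 1, 3)
                .reshape(hw * hw, p * p)
            )
            # Small bias column keeps constant (e.g. all-black) crops
            # embeddable without dominating textured ones.
            patches = np.hstack([patches, 0.05 * np.ones((patches.shape[0], 1))])
            feats = np.tanh(patches @ proj).reshape(hw, hw, -1)
            maps.append(FeatureMap(values=feats, scale_id=i))
        return maps[0], maps[1], maps[2]


def _crop_box(frame: np.ndarray, box: BoundingBox) -> np.ndarray:
    """Extract the box's pixels, clipping to the frame; error if fully outside."""
    H, W = frame.shape[:2]
    x0 = int(np.floor(max(box.x, 0)))
    y0 = int(np.floor(max(box.y, 0)))
    x1 = int(np.ceil(min(box.x + box.w, W)))
    y1 = int(np.ceil(min(box.y + box.h, H)))
    if x1 <= x0 or y1 <= y0:
        raise InvalidCropError(
            f"box ({box.x}, {box.y}, {box.w}, {box.h}) lies outside the "
            f"{W}x{H} frame"
        )
    return frame[y0:y1, x0:x1]


def embed_detections(
    frame: np.ndarray,
    boxes: Sequence[BoundingBox],
    backbone: BackboneContract,
) -> list[np.ndarray]:
    """Embed each detection crop: crop → resize → backbone → pool → fuse.

    Boxes partially outside the frame are clipped; fully-outside boxes
    raise.  Output order matches box order and every embedding has unit
    L2 norm.
    """
    out = []
    for box in boxes:
        crop = _crop_box(frame, box).astype(float)
        if crop.shape != (backbone.input_size, backbone.input_size):
            crop = resize(
                crop, (backbone.input_size, backbone.input_size), order=1,
                anti_aliasing=False, preserve_range=True,
            )
        f1, f2, f3 = backbone(crop)
        out.append(
            fuse_embeddings(
                pool_feature_map(f1), pool_feature_map(f2), pool_feature_map(f3)
            )
        )
    return out
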