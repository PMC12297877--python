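"""Track–detection association: costs, gating, assignment, cascade.

The association cost between track ``i`` and detection ``j`` blends motion
and appearance:

    C[i, j] = lambda * d2_motion(i, j) + (1 - lambda) * d_cos(i, j)

where ``d2_motion`` is the squared Mahalanobis distance of the detection's
measurement under the track's unscented measurement prediction, and
``d_cos`` is the minimum cosine distance between the detection embedding
and the track's embedding gallery.  Pairs whose motion distance exceeds a
chi-square gate (95% quantile, 4 degrees of freedom, ~9.4877) are marked
infeasible; an optional appearance gate does the same above a maximum
cosine distance.  The one-to-one assignment minimizing total cost is
solved with the Hungarian algorithm; infeasible entries are carried as a
large finite sentinel and post-filtered so the solver never sees
infinities.

The matching cascade walks track age levels 1..max_age (frames since last
match), giving recently seen tracks first claim on detections — the
DeepSORT recipe for keeping identities stable through occlusions.  An
IoU-based fallback stage serves tracks without a reliable motion gate
(tentative tracks and just-missed confirmed ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import scipy.optimize
import scipy.stats

from .appearance import cosine_distance_matrix
from .geometry import BoundingBox, box_to_measurement, iou_matrix
from .motion import MotionModel, UKFParams, gating_distance

if TYPE_CHECKING:  # pragma: no cover
    from .tracker import Track

__all__ = [
    "CHI2_GATE_95_DF4",
    "INFEASIBLE_COST",
    "CostMatrix",
    "AssignmentResult",
    "build_cost_matrix",
    "motion_distance_matrix",
    "gate_cost_matrix",
    "solve_assignment",
    "matching_cascade",
    "iou_match",
]

#: 95% chi-square quantile with 4 degrees of freedom — the default motion
#: gate for a 4-D measurement residual.
CHI2_GATE_95_DF4: float = float(scipy.stats.chi2.ppf(0.95, df=4))

#: Large finite sentinel standing in for infeasible entries during solving.
INFEASIBLE_COST = 1e5


@dataclass
class CostMatrix:
    """N tracks x M detections association costs plus an infeasibility mask."""

    costs: np.ndarray
    infeasible: np.ndarray

    def __post_init__(self) -> None:
        self.costs = np.atleast_2d(np.asarray(self.costs, dtype=float))
        self.infeasible = np.atleast_2d(np.asarray(self.infeasible, dtype=bool))
        if self.costs.shape != self.infeasible.shape:
            raise ValueError("costs and mask shapes differ")


@dataclass
class AssignmentResult:
    """One-to-one matches plus the leftover tracks and detections."""

    matches: list[tuple[int, int]] = field(default_factory=list)
    unmatched_tracks: list[int] = field(default_factory=list)
    unmatched_detections: list[int] = field(default_factory=list)


def motion_distance_matrix(
    tracks: Sequence["Track"],
    detections: Sequence[BoundingBox],
    model: MotionModel,
    params: UKFParams = UKFParams(),
) -> np.ndarray:
    """Squared Mahalanobis distance of every detection to every track."""
    zs = [box_to_measurement(d) for d in detections]
    if not tracks or not zs:
        return np.zeros((len(tracks), len(zs)))
    return np.array([gating_distance(t.state, zs, model, params) for t in tracks])


def build_cost_matrix(
    tracks: Sequence["Track"],
    detections: Sequence[BoundingBox],
    embeddings: Sequence[np.ndarray] | None,
    lambda_weight: float,
    model: MotionModel,
    params: UKFParams = UKFParams(),
    motion_d2: np.ndarray | None = None,
) -> tuple[CostMatrix, np.ndarray]:
    """Blend motion and appearance costs; returns (matrix, motion distances).

    ``embeddings`` may be None (no frames available), in which case the
    cost is purely the motion term regardless of ``lambda_weight``.  A
    track with an empty gallery likewise contributes no appearance term
    for its row.
    """
    if not 0.0 <= lambda_weight <= 1.0:
        raise ValueError(f"lambda_weight must lie in [0, 1], got {lambda_weight}")
    N, M = len(tracks), len(detections)
    if motion_d2 is None:
        motion_d2 = motion_distance_matrix(tracks, detections, model, params)
    costs = np.zeros((N, M))
    if N and M:
        if embeddings is None:
            costs = motion_d2.copy()
        else:
            E = np.array([np.asarray(e, float) for e in embeddings])
            app = np.zeros((N, M))
            for i, t in enumerate(tracks):
                if len(t.gallery) == 0:
                    app[i] = motion_d2[i]  # no appearance evidence yet
                else:
                    G = np.array(t.gallery)
                    app[i] = cosine_distance_matrix(G, E).min(axis=0)
            has_gallery = np.array([len(t.gallery) > 0 for t in tracks])
            costs = np.where(
                has_gallery[:, None],
                lambda_weight * motion_d2 + (1.0 - lambda_weight) * app,
                motion_d2,
            )
    return CostMatrix(costs=costs, infeasible=np.zeros((N, M), bool)), motion_d2


def gate_cost_matrix(
    C: CostMatrix,
    motion_d2: np.ndarray,
    threshold: float = CHI2_GATE_95_DF4,
    appearance_d: np.ndarray | None = None,
    appearance_threshold: float | None = None,
) -> CostMatrix:
    """Mark pairs with implausible motion (and optionally appearance) infeasible."""
    infeasible = C.infeasible | (motion_d2 > threshold)
    if appearance_d is not None and appearance_threshold is not None:
        infeasible = infeasible | (appearance_d > appearance_threshold)
    return CostMatrix(costs=C.costs, infeasible=infeasible)


def solve_assignment(C: CostMatrix) -> AssignmentResult:
    """Minimum-cost one-to-one assignment via the Hungarian algorithm.

    Infeasible pairs are never reported as matches.  Among equal-cost
    optima the lexicographically smallest (track, detection) pairing wins,
    enforced by an additive tie-breaking perturbation far below any real
    cost difference of interest.
    """
    N, M = C.costs.shape
    if N == 0 or M == 0:
        return AssignmentResult(
            matches=[],
            unmatched_tracks=list(range(N)),
            unmatched_detections=list(range(M)),
        )
    costs = np.where(C.infeasible, INFEASIBLE_COST, C.costs)
    # Lexicographic tie-break: strictly increasing in (i, j), total < 1e-7.
    ii, jj = np.meshgrid(np.arange(N), np.arange(M), indexing="ij")
    tie = (ii * M + jj).astype(float) * (1e-8 / (N * M))
    rows, cols = scipy.optimize.linear_sum_assignment(costs + tie)
    matches = []
    for r, c in zip(rows, cols):
        if C.infeasible[r, c]:
            continue
        matches.append((int(r), int(c)))
    matched_r = {r for r, _ in matches}
    matched_c = {c for _, c in matches}
    return AssignmentResult(
        matches=sorted(matches),
        unmatched_tracks=[i for i in range(N) if i not in matched_r],
        unmatched_detections=[j for j in range(M) if j not in matched_c],
    )


def matching_cascade(
    tracks: Sequence["Track"],
    detections: Sequence[BoundingBox],
    embeddings: Sequence[np.ndarray] | None,
    max_age: int,
    lambda_weight: float,
    model: MotionModel,
    params: UKFParams = UKFParams(),
    gate_threshold: float = CHI2_GATE_95_DF4,
) -> AssignmentResult:
    """Age-prioritized association: younger (recently seen) tracks match first.

    Level ``a`` runs build→gate→solve for the tracks with
    ``time_since_update == a`` against the detections still unmatched, for
    ``a = 1..max_age``; a detection claimed at an earlier level is
    unavailable later.
    """
    result = AssignmentResult(unmatched_detections=list(range(len(detections))))
    matched_tracks: set[int] = set()
    for age in range(1, max_age + 1):
        if not result.unmatched_detections:
            break
        level_idx = [
            i for i, t in enumerate(tracks) if t.time_since_update == age
        ]
        if not level_idx:
            continue
        det_idx = result.unmatched_detections
        level_tracks = [tracks[i] for i in level_idx]
        level_dets = [detections[j] for j in det_idx]
        level_emb = (
            None if embeddings is None else [embeddings[j] for j in det_idx]
        )
        C, d2 = build_cost_matrix(
            level_tracks, level_dets, level_emb, lambda_weight, model, params
        )
        C = gate_cost_matrix(C, d2, gate_threshold)
        sub = solve_assignment(C)
        for r, c in sub.matches:
            result.matches.append((level_idx[r], det_idx[c]))
            matched_tracks.add(level_idx[r])
        result.unmatched_detections = [det_idx[c] for c in sub.unmatched_detections]
    result.matches.sort()
    result.unmatched_tracks = [
        i for i in range(len(tracks)) if i not in matched_tracks
    ]
    return result


def iou_match(
    tracks: Sequence["Track"],
    detections: Sequence[BoundingBox],
    iou_threshold: float = 0.3,
) -> AssignmentResult:
    """Fallback association on box overlap: cost ``1 - IoU`` of the track's
    predicted box against each detection, pairs below the IoU threshold
    infeasible."""
    N, M = len(tracks), len(detections)
    if N == 0 or M == 0:
        return AssignmentResult(
            matches=[],
            unmatched_tracks=list(range(N)),
            unmatched_detections=list(range(M)),
        )
    pred_boxes = [t.predicted_box() for t in tracks]
    overlap = iou_matrix(pred_boxes, list(detections))
    C = CostMatrix(costs=1.0 - overlap, infeasible=overlap < iou_threshold)
    return solve_assignment(C)
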