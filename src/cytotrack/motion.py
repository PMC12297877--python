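"""Unscented Kalman filtering over the 8-D constant-velocity box state.

The state is ``x = (cx, cy, a, h, v_cx, v_cy, v_a, v_h)``: box center,
aspect ratio and height plus their per-frame velocities.  Dynamics are the
constant-velocity model ``x' = F x`` with block transition
``F = [[I4, dt*I4], [0, I4]]`` and linear observation ``z = H x`` with
``H = [I4 | 0]``.  Because this shipped model is linear, the UKF must agree
with an ordinary Kalman filter to numerical precision — a property the test
suite exploits as an oracle — but the sigma-point machinery accepts
arbitrary transition/observation callables so non-linear cell dynamics can
be plugged in without touching the tracker.

Sigma points follow the Merwe scaled unscented transform with defaults
``alpha=1e-3, beta=2, kappa=0``.  Covariances are symmetrized after every
step and Cholesky factorization retries with escalating diagonal jitter
(1e-9 up to 1e-3) before giving up.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.linalg

from .geometry import Measurement

__all__ = [
    "STATE_DIM",
    "MEAS_DIM",
    "TrackState",
    "MotionModel",
    "UKFParams",
    "SigmaSet",
    "make_motion_model",
    "sigma_points",
    "initiate",
    "predict",
    "update",
    "gating_distance",
    "NumericalError",
    "ConfigError",
]

STATE_DIM = 8
MEAS_DIM = 4

#: Floor applied to the aspect-ratio and height components after every
#: predict/update, keeping the state convertible back to a valid box.
MIN_SIZE = 1e-3


class NumericalError(RuntimeError):
    """Cholesky failure after maximum jitter, or a singular innovation."""


class ConfigError(ValueError):
    """Invalid filter configuration (non-positive scales, bad dt)."""


@dataclass
class TrackState:
    """Gaussian belief over the 8-D box state: mean and covariance."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(STATE_DIM)
        self.covariance = np.asarray(self.covariance, dtype=float).reshape(
            STATE_DIM, STATE_DIM
        )
        if not np.all(np.isfinite(self.mean)):
            raise ValueError("state mean must be finite")

    def measurement_mean(self) -> Measurement:
        return Measurement.from_array(self.mean[:MEAS_DIM])


@dataclass(frozen=True)
class MotionModel:
    """Constant-velocity transition, observation and noise matrices."""

    F: np.ndarray
    H: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    P0: np.ndarray
    dt: float


@dataclass(frozen=True)
class UKFParams:
    """Merwe scaled unscented-transform hyperparameters."""

    alpha: float = 1e-3
    beta: float = 2.0
    kappa: float = 0.0


@dataclass
class SigmaSet:
    """2n+1 sigma points with their mean and covariance weights."""

    points: np.ndarray  # (2n+1, n)
    mean_weights: np.ndarray  # (2n+1,)
    cov_weights: np.ndarray  # (2n+1,)

    def reconstruct(self) -> tuple[np.ndarray, np.ndarray]:
        """Recombine points into (mean, covariance) — the inverse transform."""
        mean = self.mean_weights @ self.points
        dev = self.points - mean
        cov = (self.cov_weights[:, None] * dev).T @ dev
        return mean, cov


def make_motion_model(
    dt: float = 1.0,
    q_scale: float = 0.1,
    r_scale: float = 2.0,
    p0_scale: float = 500.0,
) -> MotionModel:
    """Build the constant-velocity model with isotropic noise covariances.

    Defaults are the tracker's standard operating point: initial state
    uncertainty ``P0 = 500 I8``, process noise ``Q = 0.1 I8`` and
    observation noise ``R = 2 I4``, with a one-frame time step.
    """
    if dt < 0:
        raise ConfigError(f"dt must be non-negative, got {dt}")
    if q_scale <= 0 or r_scale <= 0 or p0_scale <= 0:
        raise ConfigError("noise scales must be positive")
    I4 = np.eye(MEAS_DIM)
    F = np.block([[I4, dt * I4], [np.zeros((4, 4)), I4]])
    H = np.hstack([I4, np.zeros((4, 4))])
    return MotionModel(
        F=F,
        H=H,
        Q=q_scale * np.eye(STATE_DIM),
        R=r_scale * np.eye(MEAS_DIM),
        P0=p0_scale * np.eye(STATE_DIM),
        dt=dt,
    )


def _symmetrize(P: np.ndarray) -> np.ndarray:
    return (P + P.T) / 2.0


def _safe_cholesky(P: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor, retrying with escalating diagonal jitter."""
    P = _symmetrize(P)
    try:
        return np.linalg.cholesky(P)
    except np.linalg.LinAlgError:
        pass
    jitter = 1e-9
    while jitter <= 1e-3:
        try:
            return np.linalg.cholesky(P + jitter * np.eye(P.shape[0]))
        except np.linalg.LinAlgError:
            jitter *= 10.0
    raise NumericalError(
        "covariance not positive definite even after 1e-3 diagonal jitter; "
        f"diagonal = {np.diag(P)}"
    )


def sigma_points(
    state: TrackState, params: UKFParams = UKFParams()
) -> SigmaSet:
    """Merwe scaled sigma points for an 8-D Gaussian belief.

    Point 0 is the mean; points ``i`` and ``i+n`` sit symmetrically about
    the mean along the columns of the scaled Cholesky factor.  Mean weights
    sum to one; reconstructing mean and covariance from the set recovers
    the inputs exactly (up to round-off).
    """
    n = state.mean.shape[0]
    lam = params.alpha**2 * (n + params.kappa) - n
    L = _safe_cholesky((n + lam) * state.covariance)
    pts = np.empty((2 * n + 1, n))
    pts[0] = state.mean
    pts[1 : n + 1] = state.mean + L.T
    pts[n + 1 :] = state.mean - L.T
    wm = np.full(2 * n + 1, 1.0 / (2.0 * (n + lam)))
    wc = wm.copy()
    wm[0] = lam / (n + lam)
    wc[0] = lam / (n + lam) + (1.0 - params.alpha**2 + params.beta)
    return SigmaSet(points=pts, mean_weights=wm, cov_weights=wc)


def initiate(z: Measurement, model: MotionModel) -> TrackState:
    """Start a belief from a first detection: zero velocities, covariance P0."""
    mean = np.zeros(STATE_DIM)
    mean[:MEAS_DIM] = z.to_array()
    return TrackState(mean=mean, covariance=model.P0.copy())


def _clamp_state(mean: np.ndarray) -> np.ndarray:
    # a and h can drift non-positive through the linear dynamics; floor them
    # so the state always maps back to a valid box.
    mean = mean.copy()
    mean[2] = max(mean[2], MIN_SIZE)
    mean[3] = max(mean[3], MIN_SIZE)
    return mean


def predict(
    state: TrackState,
    model: MotionModel,
    params: UKFParams = UKFParams(),
    transition: Callable[[np.ndarray], np.ndarray] | None = None,
) -> TrackState:
    """One-step time update via the unscented transform.

    ``transition`` maps a state vector to its successor; it defaults to the
    model's linear ``x -> F x``, in which case the result coincides with the
    linear Kalman prediction ``(F m, F P F^T + Q)``.
    """
    f = transition if transition is not None else (lambda x: model.F @ x)
    sig = sigma_points(state, params)
    prop = np.array([f(p) for p in sig.points])
    mean = sig.mean_weights @ prop
    dev = prop - mean
    cov = (sig.cov_weights[:, None] * dev).T @ dev + model.Q
    return TrackState(mean=_clamp_state(mean), covariance=_symmetrize(cov))


def _measurement_prediction(
    state: TrackState,
    model: MotionModel,
    params: UKFParams,
    observation: Callable[[np.ndarray], np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predicted measurement mean, innovation covariance S, cross-covariance."""
    h = observation if observation is not None else (lambda x: model.H @ x)
    sig = sigma_points(state, params)
    Z = np.array([h(p) for p in sig.points])
    z_hat = sig.mean_weights @ Z
    dz = Z - z_hat
    S = (sig.cov_weights[:, None] * dz).T @ dz + model.R
    dx = sig.points - sig.mean_weights @ sig.points
    T = (sig.cov_weights[:, None] * dx).T @ dz
    return z_hat, _symmetrize(S), T


def update(
    state: TrackState,
    z: Measurement,
    model: MotionModel,
    params: UKFParams = UKFParams(),
    observation: Callable[[np.ndarray], np.ndarray] | None = None,
) -> TrackState:
    """Measurement update: fold a detection into the predicted belief.

    With the default linear observation the result matches the linear
    Kalman update.  The posterior covariance is symmetrized; aspect ratio
    and height are floored at a small positive value.
    """
    z_hat, S, T = _measurement_prediction(state, model, params, observation)
    try:
        chol = scipy.linalg.cho_factor(S, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise NumericalError(f"singular innovation covariance: {exc}") from exc
    K = scipy.linalg.cho_solve(chol, T.T).T  # K = T S^-1
    innovation = z.to_array() - z_hat
    mean = state.mean + K @ innovation
    cov = state.covariance - K @ S @ K.T
    return TrackState(mean=_clamp_state(mean), covariance=_symmetrize(cov))


def gating_distance(
    state: TrackState,
    zs: Sequence[Measurement],
    model: MotionModel,
    params: UKFParams = UKFParams(),
) -> np.ndarray:
    """Squared Mahalanobis distance of each measurement to the track.

    ``d2[j] = (z_j - z_hat)^T S^-1 (z_j - z_hat)`` with the predicted
    measurement ``z_hat`` and innovation covariance ``S`` from the
    unscented measurement prediction.  Call on a state already predicted
    for the current frame.
    """
    if len(zs) == 0:
        return np.zeros(0)
    z_hat, S, _ = _measurement_prediction(state, model, params)
    residuals = np.array([z.to_array() for z in zs]) - z_hat
    try:
        chol = scipy.linalg.cho_factor(S, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise NumericalError(f"singular innovation covariance: {exc}") from exc
    solved = scipy.linalg.cho_solve(chol, residuals.T)
    return np.einsum("ij,ji->i", residuals, solved)
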