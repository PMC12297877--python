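import numpy as np
import pytest

from cytotrack.motion import TrackState, UKFParams, make_motion_model


@pytest.fixture(scope="session")
def model():
    """Default constant-velocity model (dt=1, P0=500 I8, Q=0.1 I8, R=2 I4)."""
    return make_motion_model()


@pytest.fixture(scope="session")
def ukf_params():
    return UKFParams()


def random_state(rng: np.random.Generator) -> TrackState:
    """A random but physically sensible track state with a PSD covariance.

    Positions in-frame, positive aspect ratio and height, moderate
    velocities; covariance built as A A^T plus a diagonal bump.
    """
    mean = np.array(
        [
            rng.uniform(50, 1500),
            rng.uniform(50, 1100),
            rng.uniform(0.6, 2.5),
            rng.uniform(15, 80),
            rng.normal(0, 3),
            rng.normal(0, 3),
            rng.normal(0, 0.05),
            rng.normal(0, 1),
        ]
    )
    A = rng.normal(size=(8, 8))
    cov = A @ A.T + 5.0 * np.eye(8)
    return TrackState(mean=mean, covariance=cov)


class LinearKalmanFilter:
    """Independent textbook linear KF used as an oracle for the UKF.

    Implemented directly from the standard predict/update equations,
    sharing no code with the filter under test.
    """

    def __init__(self, model):
        self.F, self.H = model.F, model.H
        self.Q, self.R = model.Q, model.R

    def predict(self, mean, cov):
        mean = self.F @ mean
        cov = self.F @ cov @ self.F.T + self.Q
        return mean, cov

    def update(self, mean, cov, z):
        S = self.H @ cov @ self.H.T + self.R
        K = cov @ self.H.T @ np.linalg.inv(S)
        mean = mean + K @ (z - self.H @ mean)
        cov = (np.eye(len(mean)) - K @ self.H) @ cov
        return mean, cov
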