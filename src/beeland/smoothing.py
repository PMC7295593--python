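"""Fixed-interval Kalman (RTS) smoothing of raw 3D landmark tracks.

Each spatial axis is smoothed independently under a constant-acceleration
state model with state ``[position, velocity, acceleration]``::

    F = [[1, dt, dt^2/2],
         [0,  1, dt    ],
         [0,  0, 1     ]]        H = [1, 0, 0]

The process-noise covariance is diagonal with entries (1, 0.1, 0.01) on the
position, velocity and acceleration states and the measurement-noise
covariance is the identity scale (scalar 1 per axis), with zero
cross-covariance. These are the defaults of :class:`SmootherSpec`; units
follow the track units (metres). A forward filter pass is followed by a
backward Rauch–Tung–Striebel pass, so every output frame conditions on the
whole track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class SmootherSpec:
    """Noise configuration of the trajectory smoother.

    dt : frame interval in seconds (0.01 s at 100 frames per second).
    process_noise_diag : diagonal of Q on [position, velocity, acceleration].
    measurement_noise : scalar R per axis.
    initial_covariance : diagonal of P0 (large: the first frames burn in).
    """

    dt: float = 0.01
    process_noise_diag: tuple[float, float, float] = (1.0, 0.1, 0.01)
    measurement_noise: float = 1.0
    # effectively diffuse: with the default noise ratios the per-frame data
    # information about velocity is tiny, so a merely "large" P0 would pull
    # velocity estimates toward the zero initial state deep into the track
    initial_covariance: float = 1e6

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if min(self.process_noise_diag) <= 0 or self.measurement_noise <= 0:
            raise ValueError("noise entries must be positive")


@dataclass
class Trajectory3D:
    """Smoothed head kinematics plus abdomen-tip position on a common time base.

    ``t`` is seconds per frame (constant step), ``X``/``U``/``A`` are (n, 3)
    head position, velocity and acceleration, ``X_abd`` the abdomen-tip
    position. ``aligned`` records whether touchdown is t=0 at the origin.
    """

    t: np.ndarray
    X: np.ndarray
    U: np.ndarray
    A: np.ndarray
    X_abd: np.ndarray | None = None
    aligned: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("X", "U", "A"):
            arr = getattr(self, name)
            if arr.shape != (n, 3):
                raise ValueError(f"{name} must be (n, 3) with n = len(t)")
        if self.X_abd is not None and self.X_abd.shape != (n, 3):
            raise ValueError("X_abd must match the time base")
        dts = np.diff(self.t)
        if n > 1 and (np.any(dts <= 0) or not np.allclose(dts, dts[0], rtol=1e-6)):
            raise ValueError("t must be strictly increasing with constant step")
        if not np.all(np.isfinite(self.U)):
            raise ValueError("velocities must be finite")

    @property
    def n_frames(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else np.nan

    @property
    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.U, axis=1)


def _rts_single_axis(z: np.ndarray, spec: SmootherSpec) -> np.ndarray:
    """Forward filter + backward RTS pass on one axis. Returns (n, 3) states."""
    dt = spec.dt
    F = np.array([[1.0, dt, 0.5 * dt * dt], [0.0, 1.0, dt], [0.0, 0.0, 1.0]])
    H = np.array([[1.0, 0.0, 0.0]])
    Q = np.diag(spec.process_noise_diag)
    R = spec.measurement_noise
    n = len(z)

    x_pred = np.zeros((n, 3))
    P_pred = np.zeros((n, 3, 3))
    x_filt = np.zeros((n, 3))
    P_filt = np.zeros((n, 3, 3))

    x = np.array([z[0], 0.0, 0.0])
    P = np.eye(3) * spec.initial_covariance
    for k in range(n):
        if k > 0:
            x = F @ x
            P = F @ P @ F.T + Q
        x_pred[k], P_pred[k] = x, P
        # scalar measurement update
        S = P[0, 0] + R
        K = P[:, 0] / S
        x = x + K * (z[k] - x[0])
        P = P - np.outer(K, P[0, :])
        x_filt[k], P_filt[k] = x, P

    x_smooth = np.zeros((n, 3))
    x_smooth[-1] = x_filt[-1]
    P_s = P_filt[-1]
    for k in range(n - 2, -1, -1):
        C = P_filt[k] @ F.T @ np.linalg.inv(P_pred[k + 1])
        x_smooth[k] = x_filt[k] + C @ (x_smooth[k + 1] - x_pred[k + 1])
        P_s = P_filt[k] + C @ (P_s - P_pred[k + 1]) @ C.T
    return x_smooth


def smooth_positions(raw: np.ndarray, spec: SmootherSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smooth an ``(n, 3)`` raw position track into position/velocity/acceleration."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != 3:
        raise ValueError("raw positions must be (n, 3)")
    if len(raw) < 5:
        raise ValueError("at least 5 frames are required")
    bad = np.where(~np.all(np.isfinite(raw), axis=1))[0]
    if bad.size:
        raise ValueError(f"non-finite input at frame {int(bad[0])}")
    states = np.stack([_rts_single_axis(raw[:, ax], spec) for ax in range(3)], axis=-1)
    # states: (n, 3 state components, 3 axes)
    return states[:, 0, :], states[:, 1, :], states[:, 2, :]


def smooth_trajectory(
    raw_head: np.ndarray,
    spec: SmootherSpec,
    raw_abdomen: np.ndarray | None = None,
    t0: float = 0.0,
) -> Trajectory3D:
    """Smooth raw head (and optionally abdomen-tip) tracks into a trajectory.

    Head and abdomen are smoothed independently; the abdomen contributes only
    its position (the body-pitch input). The returned trajectory is unaligned.
    """
    X, U, A = smooth_positions(raw_head, spec)
    X_abd = None
    if raw_abdomen is not None:
        if len(raw_abdomen) != len(raw_head):
            raise ValueError("head and abdomen tracks must have equal length")
        X_abd, _, _ = smooth_positions(np.asarray(raw_abdomen, dtype=float), spec)
    t = t0 + spec.dt * np.arange(len(raw_head))
    return Trajectory3D(t=t, X=X, U=U, A=A, X_abd=X_abd, aligned=False)
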