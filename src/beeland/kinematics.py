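"""Touchdown alignment and per-frame landing kinematics.

World convention (asserted by the test suite): the z-axis points downward,
so flight height relative to the landing point is ``h = -z``; touchdown
defines both the spatial origin and t = 0, with approach time negative.

Per-frame series, with touchdown at the final frame of an aligned track:

* ``d_E`` — Euclidean distance to the landing point, |X(t)|.
* ``h`` — flight height, −z(t).
* ``speed`` — |U(t)| from the smoother.
* ``U_P`` — speed towards the platform, −d(d_E)/dt by central differences
  (positive when approaching).
* ``d`` — remaining path length to touchdown: the sum of per-frame
  central-difference displacements |ΔX(i)| = |X(i+1) − X(i−1)|/2 between the
  frame and touchdown (one-sided at the track ends, empty sum at touchdown).
* ``tau`` — tortuosity d/d_E (≥ 1 up to discretisation; NaN at d_E = 0).
* ``beta`` — body pitch: angle of the head→abdomen-tip axis above the
  horizontal plane, positive when the head is above the abdomen tip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .smoothing import Trajectory3D


class EmptyManoeuvreError(ValueError):
    """Touchdown at the very first frame leaves nothing to analyse."""


@dataclass
class KinematicSeries:
    """Per-frame kinematic series sharing an aligned trajectory's time base."""

    t: np.ndarray
    d_E: np.ndarray
    h: np.ndarray
    speed: np.ndarray
    U_P: np.ndarray
    d: np.ndarray
    tau: np.ndarray
    beta: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return len(self.t)


def align_to_touchdown(traj: Trajectory3D, touchdown_frame: int) -> Trajectory3D:
    """Shift time and position so touchdown is t=0 at the origin.

    Frames after ``touchdown_frame`` are dropped; aligning an already-aligned
    track is idempotent.
    """
    if not 0 <= touchdown_frame < traj.n_frames:
        raise IndexError("touchdown_frame outside track")
    if touchdown_frame == 0:
        raise EmptyManoeuvreError("touchdown at frame 0: no approach to analyse")
    sl = slice(0, touchdown_frame + 1)
    X0 = traj.X[touchdown_frame]
    return Trajectory3D(
        t=traj.t[sl] - traj.t[touchdown_frame],
        X=traj.X[sl] - X0,
        U=traj.U[sl].copy(),
        A=traj.A[sl].copy(),
        X_abd=None if traj.X_abd is None else traj.X_abd[sl] - X0,
        aligned=True,
        meta=dict(traj.meta),
    )


def _central_diff(y: np.ndarray, dx: float = 1.0) -> np.ndarray:
    """Central differences with one-sided endpoints (same length as input)."""
    y = np.asarray(y, dtype=float)
    out = np.empty_like(y)
    out[1:-1] = (y[2:] - y[:-2]) / 2.0
    out[0] = y[1] - y[0]
    out[-1] = y[-1] - y[-2]
    return out / dx


def path_length_series(traj: Trajectory3D) -> np.ndarray:
    """Remaining path length d(I) from each frame to touchdown.

    Per-frame displacement magnitudes come from a central-difference scheme on
    the position vector (one-sided at the ends); d at touchdown is 0 and the
    series is non-increasing towards touchdown.
    """
    if not traj.aligned:
        raise ValueError("trajectory must be aligned to touchdown")
    if traj.n_frames < 3:
        raise ValueError("at least 3 frames required")
    steps = np.linalg.norm(
        np.stack([_central_diff(traj.X[:, ax]) for ax in range(3)], axis=1), axis=1
    )
    # d(I) = sum of steps strictly after frame I (empty at touchdown)
    rev = np.concatenate([[0.0], np.cumsum(steps[:0:-1])])[::-1]
    return rev


def euclidean_series(traj: Trajectory3D) -> np.ndarray:
    return np.linalg.norm(traj.X, axis=1)


def tortuosity_series(d: np.ndarray, d_E: np.ndarray) -> np.ndarray:
    """Tortuosity τ = d/d_E; frames with d_E = 0 are NaN (undefined)."""
    d = np.asarray(d, dtype=float)
    d_E = np.asarray(d_E, dtype=float)
    if d.shape != d_E.shape:
        raise ValueError("series must share length")
    if np.any(d < 0) or np.any(d_E < 0):
        raise ValueError("path length and distance must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.where(d_E > 0, d / d_E, np.nan)
    return tau


def approach_speed_series(d_E: np.ndarray, dt: float) -> np.ndarray:
    """Speed towards the platform, U_P = −d(d_E)/dt (central differences)."""
    d_E = np.asarray(d_E, dtype=float)
    if len(d_E) < 3:
        raise ValueError("at least 3 frames required")
    return -_central_diff(d_E, dt)


def body_pitch_series(head: np.ndarray, abdomen: np.ndarray) -> np.ndarray:
    """Body pitch β in degrees from head and abdomen-tip positions.

    β = arcsin(Δh / |body|), Δh the height difference head minus abdomen tip
    (heights h = −z). Zero-length body vectors yield NaN.
    """
    head = np.atleast_2d(np.asarray(head, dtype=float))
    abdomen = np.atleast_2d(np.asarray(abdomen, dtype=float))
    body = head - abdomen
    length = np.linalg.norm(body, axis=1)
    dh = -(head[:, 2] - abdomen[:, 2])  # h = -z
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.degrees(np.arcsin(np.clip(dh / length, -1.0, 1.0)))
    beta[length == 0] = np.nan
    return beta


def compute_kinematics(traj: Trajectory3D) -> KinematicSeries:
    """All per-frame kinematic series of one aligned trajectory."""
    if not traj.aligned:
        raise ValueError("trajectory must be aligned to touchdown")
    d_E = euclidean_series(traj)
    d = path_length_series(traj)
    beta = None
    if traj.X_abd is not None:
        beta = body_pitch_series(traj.X, traj.X_abd)
    return KinematicSeries(
        t=traj.t,
        d_E=d_E,
        h=-traj.X[:, 2],
        speed=traj.speed,
        U_P=approach_speed_series(d_E, traj.dt),
        d=d,
        tau=tortuosity_series(d, d_E),
        beta=beta,
    )
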