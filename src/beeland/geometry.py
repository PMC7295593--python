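"""Direct linear transformation (DLT) camera calibration and two-view triangulation.

A camera is the classical 11-coefficient DLT mapping from 3D world
coordinates (metres) to 2D pixel coordinates::

    u = (L1*x + L2*y + L3*z + L4) / (L9*x + L10*y + L11*z + 1)
    v = (L5*x + L6*y + L7*z + L8) / (L9*x + L10*y + L11*z + 1)

Pixel origin is top-left, u rightward, v downward. Calibration solves the
linear least-squares system over >=6 non-coplanar control points; two
calibrated views reconstruct a 3D point frame-wise by stacking both cameras'
two equations into a 4x3 least-squares system. No lens distortion terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: condition number above which a stereo geometry is flagged degenerate
CONDITION_LIMIT = 1e8


class CalibrationDegenerateError(ValueError):
    """Rig correspondences do not determine the 11 DLT coefficients."""


class UnreliableGeometryError(ValueError):
    """Viewing rays are (near-)parallel; triangulation would be unstable."""


@dataclass(frozen=True)
class CameraModel:
    """One calibrated camera: 11 DLT coefficients (L1..L11)."""

    dlt: np.ndarray
    image_size: tuple[int, int] = (1280, 1024)

    def __post_init__(self) -> None:
        dlt = np.asarray(self.dlt, dtype=float)
        if dlt.shape != (11,) or not np.all(np.isfinite(dlt)):
            raise ValueError("dlt must be 11 finite coefficients")
        object.__setattr__(self, "dlt", dlt)

    def project(self, points3d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project ``(n, 3)`` world points to ``(n, 2)`` pixels.

        Returns ``(uv, valid)`` where ``valid`` flags frames whose DLT
        denominator is safely nonzero; invalid frames carry NaN pixels.
        """
        P = np.atleast_2d(np.asarray(points3d, dtype=float))
        L = self.dlt
        den = P @ L[8:11] + 1.0
        valid = np.abs(den) > 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            u = (P @ L[0:3] + L[3]) / den
            v = (P @ L[4:7] + L[7]) / den
        uv = np.column_stack([u, v])
        uv[~valid] = np.nan
        return uv, valid


@dataclass
class RigCorrespondences:
    """Calibration-rig control points and their pixel observations in one camera."""

    world: np.ndarray  # (n, 3) metres
    image: np.ndarray  # (n, 2) pixels

    def __post_init__(self) -> None:
        self.world = np.asarray(self.world, dtype=float)
        self.image = np.asarray(self.image, dtype=float)
        if self.world.ndim != 2 or self.world.shape[1] != 3:
            raise ValueError("world must be (n, 3)")
        if self.image.shape != (self.world.shape[0], 2):
            raise ValueError("image must be (n, 2) matching world")
        if len(self.world) < 6:
            raise ValueError("at least 6 point correspondences are required")


@dataclass
class CalibrationResult:
    camera: CameraModel
    rmse_px: float
    residuals_px: np.ndarray = field(repr=False)


def _design_matrix(world: np.ndarray, image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = len(world)
    x, y, z = world.T
    u, v = image.T
    A = np.zeros((2 * n, 11))
    A[0::2, 0:3] = world
    A[0::2, 3] = 1.0
    A[0::2, 8] = -u * x
    A[0::2, 9] = -u * y
    A[0::2, 10] = -u * z
    A[1::2, 4:7] = world
    A[1::2, 7] = 1.0
    A[1::2, 8] = -v * x
    A[1::2, 9] = -v * y
    A[1::2, 10] = -v * z
    b = np.empty(2 * n)
    b[0::2] = u
    b[1::2] = v
    return A, b


def calibrate_dlt(rig: RigCorrespondences, image_size: tuple[int, int] = (1280, 1024)) -> CalibrationResult:
    """Solve the 11 DLT coefficients by linear least squares.

    Raises :class:`CalibrationDegenerateError` when the design matrix has
    rank < 11 (e.g. coplanar control points).
    """
    A, b = _design_matrix(rig.world, rig.image)
    if np.linalg.matrix_rank(A, tol=None) < 11:
        raise CalibrationDegenerateError(
            "rig is degenerate (coplanar or ill-placed control points): "
            "DLT design matrix rank < 11"
        )
    L, *_ = np.linalg.lstsq(A, b, rcond=None)
    cam = CameraModel(dlt=L, image_size=image_size)
    uv, _ = cam.project(rig.world)
    residuals = np.linalg.norm(uv - rig.image, axis=1)
    rmse = float(np.sqrt(np.mean(residuals**2)))
    return CalibrationResult(camera=cam, rmse_px=rmse, residuals_px=residuals)


def reprojection_report(cam: CameraModel, rig: RigCorrespondences) -> dict:
    """Per-point reprojection residuals for calibration QC."""
    uv, _ = cam.project(rig.world)
    res = np.linalg.norm(uv - rig.image, axis=1)
    return {
        "residuals_px": res,
        "mean_px": float(res.mean()),
        "max_px": float(res.max()),
        "rmse_px": float(np.sqrt(np.mean(res**2))),
        "argmax": int(res.argmax()),
    }


def triangulate(
    cam1: CameraModel,
    cam2: CameraModel,
    uv1: np.ndarray,
    uv2: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Reconstruct one 3D point from its two pixel observations.

    Stacks both cameras' two DLT equations into a 4x3 linear least-squares
    system. Returns ``(point, residual)`` where ``residual`` is the RMS of the
    4 equation residuals. Raises :class:`UnreliableGeometryError` when the
    system's condition number exceeds ``CONDITION_LIMIT``.
    """
    uv1 = np.asarray(uv1, dtype=float)
    uv2 = np.asarray(uv2, dtype=float)
    if not (np.all(np.isfinite(uv1)) and np.all(np.isfinite(uv2))):
        raise ValueError("pixel observations must be finite")
    rows = []
    rhs = []
    for cam, (u, v) in ((cam1, uv1), (cam2, uv2)):
        L = cam.dlt
        rows.append([L[0] - u * L[8], L[1] - u * L[9], L[2] - u * L[10]])
        rows.append([L[4] - v * L[8], L[5] - v * L[9], L[6] - v * L[10]])
        rhs.append(u - L[3])
        rhs.append(v - L[7])
    A = np.array(rows)
    b = np.array(rhs)
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise UnreliableGeometryError(
            f"stereo geometry unreliable (condition number {cond:.3g})"
        )
    X, res, *_ = np.linalg.lstsq(A, b, rcond=None)
    residual = float(np.sqrt(res[0] / 4.0)) if res.size else float(
        np.sqrt(np.mean((A @ X - b) ** 2))
    )
    return X, residual


def triangulate_track(
    cam1: CameraModel,
    cam2: CameraModel,
    uv1: np.ndarray,
    uv2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frame-wise triangulation of ``(n, 2)`` pixel tracks.

    Frames with non-finite pixels or degenerate geometry come back as NaN
    with ``valid=False`` rather than a fabricated point.

    Returns ``(points (n,3), residuals (n,), valid (n,))``.
    """
    uv1 = np.atleast_2d(np.asarray(uv1, dtype=float))
    uv2 = np.atleast_2d(np.asarray(uv2, dtype=float))
    if uv1.shape != uv2.shape:
        raise ValueError("tracks must have identical frame counts across cameras")
    n = len(uv1)
    pts = np.full((n, 3), np.nan)
    res = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for i in range(n):
        if not (np.all(np.isfinite(uv1[i])) and np.all(np.isfinite(uv2[i]))):
            continue
        try:
            pts[i], res[i] = triangulate(cam1, cam2, uv1[i], uv2[i])
        except UnreliableGeometryError:
            continue
        valid[i] = True
    return pts, res, valid
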