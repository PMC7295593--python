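"""Synthetic landing flights, camera scenes, study designs and lamp spectra.

The generator provides ground truth for every downstream stage:

* a kinematic landing model — a bee cruises toward the landing target,
  performs one or more hovering dips (smooth Gaussian-shaped reductions of
  the approach speed), decelerates into a slow final approach, extends its
  legs ~9 mm from the target and touches down at the origin;
* two calibrated stereo cameras (top and side view, ~1 m from a
  0.5 x 0.5 x 0.5 m working volume at 100 frames per second) that project
  head and abdomen-tip landmarks with i.i.d. Gaussian pixel noise;
* a study design with a light-condition fixed effect (multiplicative on the
  natural scale for positive metrics, additive for heights and pitch),
  day-level random intercepts shared within a day, and residual noise;
* broad-spectrum white and red-blue (455/660 nm) lamp spectra.

World convention: z points down, touchdown is the origin, approach time is
negative. All randomness flows from explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .geometry import CameraModel
from .kinematics import compute_kinematics
from .segmentation import (
    DEFAULT_DISTANCE_CAP,
    DEFAULT_SPEED_CAP,
    DEFAULT_SPEED_THRESHOLD,
    LandingAnnotation,
    PhaseWindows,
    detect_tl_start,
)
from .smoothing import Trajectory3D
from .spectral import Spectrum

__all__ = [
    "FlightParams",
    "StudyDesign",
    "SyntheticScene",
    "generate_landing_trajectory",
    "generate_scene",
    "generate_study_dataset",
    "generate_calibration_rig",
    "project_to_camera",
    "generate_spectra",
    "make_default_cameras",
    "make_camera",
]


# ---------------------------------------------------------------------------
# flight trajectories


@dataclass(frozen=True)
class FlightParams:
    """Ground-truth parameters of one synthetic landing flight.

    approach_speed : cruise speed toward the target, m/s.
    hover_times : seconds before touchdown of each hovering dip.
    hover_depth : approach-speed scale reached inside a hover, m/s (the dip
        bottoms out at half this value); must sit below the hover-detection
        threshold used downstream.
    le_distance : Euclidean distance at leg extension, m.
    tortuosity_gain : amplitude (rad) of the sinusoidal heading oscillation;
        0 gives a straight approach.
    pitch_mean : body pitch, degrees (head above abdomen tip).
    body_length : head to abdomen-tip distance, m.
    final_speed : approach speed in the last ~0.5 s before touchdown, m/s.
    noise_sd_3d : optional 3D measurement noise added before smoothing tests.
    """

    approach_speed: float = 0.12
    hover_times: tuple[float, ...] = (1.0,)
    hover_depth: float = 0.02
    le_distance: float = 0.009
    tortuosity_gain: float = 0.45
    pitch_mean: float = 40.0
    body_length: float = 0.014
    frame_rate: float = 100.0
    duration: float = 3.0
    noise_sd_3d: float = 0.0
    final_speed: float = 0.06
    hover_width: float = 0.06
    osc_freq: float = 2.5
    descent_slope: float = 0.15

    def __post_init__(self) -> None:
        if self.approach_speed <= 0:
            raise ValueError("approach_speed must be positive")
        if self.le_distance <= 0 or self.body_length <= 0:
            raise ValueError("le_distance and body_length must be positive")
        if self.frame_rate <= 0 or self.duration <= 0:
            raise ValueError("frame_rate and duration must be positive")
        if self.hover_times and max(self.hover_times) + 0.3 > self.duration:
            raise ValueError(
                f"duration {self.duration} s too short to fit hovers at "
                f"{self.hover_times} s before touchdown (need "
                f"{max(self.hover_times) + 0.3:.2f} s)"
            )


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _speed_profile(tb: np.ndarray, p: FlightParams) -> np.ndarray:
    """Signed along-track speed as a function of time before touchdown.

    Inside a hover dip the speed crosses slightly below zero (the bee briefly
    backs away), emulating the hovering wobble that makes real approach
    speeds oscillate around zero.
    """
    v_final = min(p.final_speed, p.approach_speed)
    ramp = 0.5
    v = v_final + (p.approach_speed - v_final) * _smoothstep(tb / ramp)
    for h in p.hover_times:
        v_at = v_final + (p.approach_speed - v_final) * _smoothstep(np.array([h / ramp]))[0]
        depth = -0.3 * p.hover_depth / v_at
        v = v * (1.0 - (1.0 - depth) * np.exp(-((tb - h) ** 2) / (2.0 * p.hover_width**2)))
    return v


def generate_landing_trajectory(
    params: FlightParams,
    seed: int,
    threshold: float = DEFAULT_SPEED_THRESHOLD,
) -> tuple[Trajectory3D, PhaseWindows]:
    """Generate one noise-free landing flight and its ground-truth phases.

    The head path is integrated backwards from touchdown at the origin from a
    velocity field ``v(t) * u(t)``: ``v`` the approach-speed profile (cruise,
    Gaussian hover dips, slow final approach) and ``u`` a unit direction that
    oscillates in heading with amplitude ``tortuosity_gain`` and descends at
    ``descent_slope`` (the bee approaches from slightly below the target).
    The abdomen tip sits ``body_length`` behind the head at ``pitch_mean``.

    Ground-truth phase annotations come from the realised noise-free
    kinematics: leg extension at the final crossing of ``le_distance`` and
    the first hover by the same threshold rule the segmentation stage uses.
    """
    rng = np.random.default_rng(seed)
    p = params
    n = int(round(p.duration * p.frame_rate)) + 1
    t = np.linspace(-p.duration, 0.0, n)
    dt = 1.0 / p.frame_rate
    tb = -t

    v = _speed_profile(tb, p)
    phase0 = rng.uniform(0, 2 * np.pi)
    psi = p.tortuosity_gain * np.sin(2 * np.pi * p.osc_freq * tb + phase0)
    gamma = p.descent_slope
    ch = np.sqrt(1.0 - gamma**2)

    V = np.column_stack(
        [-v * np.cos(psi) * ch, v * np.sin(psi) * ch, -v * gamma]
    )
    # integrate position so the path ends exactly at the origin at touchdown
    I = cumulative_trapezoid(V, t, axis=0, initial=0.0)
    X = I - I[-1]
    A = np.gradient(V, dt, axis=0)

    beta = np.radians(p.pitch_mean)
    X_abd = X + p.body_length * np.column_stack(
        [np.cos(beta) * np.cos(psi), -np.cos(beta) * np.sin(psi), np.full(n, np.sin(beta))]
    )

    traj = Trajectory3D(t=t, X=X, U=V, A=A, X_abd=X_abd, aligned=True)

    kin = compute_kinematics(traj)
    le_frame = _le_frame_from_distance(kin.d_E, p.le_distance)
    tl_frame = detect_tl_start(kin, threshold)
    windows = PhaseWindows(
        tl_start_frame=tl_frame,
        le_start_frame=le_frame,
        touchdown_frame=n - 1,
        tl_valid=tl_frame is not None,
        le_valid=True,
        tl_reason="ok" if tl_frame is not None else "no_hover_found",
        le_reason="ok",
    )
    return traj, windows


def _le_frame_from_distance(d_E: np.ndarray, le_distance: float) -> int:
    """Frame of the final inward crossing of the leg-extension distance."""
    below = d_E <= le_distance
    if not below.any():
        raise ValueError("trajectory never reaches the leg-extension distance")
    crossings = np.where(~below[:-1] & below[1:])[0]
    if crossings.size == 0:
        idx = int(np.argmax(below))
        return idx
    k = int(crossings[-1])
    # pick whichever neighbour of the crossing sits closest to le_distance
    return k if abs(d_E[k] - le_distance) < abs(d_E[k + 1] - le_distance) else k + 1


# ---------------------------------------------------------------------------
# cameras and scenes


def make_camera(
    position: np.ndarray,
    rotation: np.ndarray,
    focal_px: float = 2560.0,
    principal: tuple[float, float] = (640.0, 512.0),
    image_size: tuple[int, int] = (1280, 1024),
) -> CameraModel:
    """Build a DLT camera from pinhole parameters.

    ``rotation`` rows are the camera axes (x right, y down, z optical)
    expressed in world coordinates; ``position`` is the camera centre.
    """
    R = np.asarray(rotation, dtype=float)
    C = np.asarray(position, dtype=float)
    K = np.array(
        [[focal_px, 0.0, principal[0]], [0.0, focal_px, principal[1]], [0.0, 0.0, 1.0]]
    )
    P = K @ np.hstack([R, (-R @ C)[:, None]])
    if abs(P[2, 3]) < 1e-12:
        raise ValueError("camera centre on the world origin's principal plane")
    L = P / P[2, 3]
    dlt = np.concatenate([L[0, :4], L[1, :4], L[2, :3]])
    return CameraModel(dlt=dlt, image_size=image_size)


def make_default_cameras() -> tuple[CameraModel, CameraModel]:
    """Top and side cameras 1 m from the origin, orthogonal optical axes."""
    top = make_camera(
        position=np.array([0.0, 0.0, -1.0]),
        rotation=np.eye(3),  # optical axis +z (downward)
    )
    side = make_camera(
        position=np.array([0.0, -1.0, 0.0]),
        rotation=np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0], [0.0, 1.0, 0.0]]),
    )
    return top, side


def project_to_camera(
    points3d: np.ndarray,
    camera: CameraModel,
    pixel_noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Project 3D points to pixels with optional i.i.d. Gaussian pixel noise.

    Returns ``(uv, valid)``; frames on the camera's principal plane are
    flagged invalid and carry NaN.
    """
    uv, valid = camera.project(points3d)
    if pixel_noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        uv = uv + rng.normal(0.0, pixel_noise_sd, size=uv.shape)
    return uv, valid


def generate_calibration_rig(
    n_points: int, extent: float = 0.5, seed: int | None = None
) -> np.ndarray:
    """Random non-coplanar control points inside an ``extent``-sized cube."""
    if n_points < 6:
        raise ValueError("DLT calibration needs at least 6 control points")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        pts = rng.uniform(-extent / 2.0, extent / 2.0, size=(n_points, 3))
        centred = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centred, tol=1e-6 * extent) == 3:
            return pts
    raise RuntimeError("failed to draw a non-coplanar rig")  # pragma: no cover


@dataclass
class SyntheticScene:
    """One synthetic landing as seen by the stereo rig."""

    ground_truth: Trajectory3D
    annotations: PhaseWindows
    tracks: dict  # camera name -> dict(head=(n,2), abd=(n,2))
    cameras: tuple[CameraModel, CameraModel]
    design_row: dict = field(default_factory=dict)


def generate_scene(
    params: FlightParams,
    seed: int,
    pixel_noise_sd: float = 0.5,
    cameras: tuple[CameraModel, CameraModel] | None = None,
    design_row: dict | None = None,
) -> SyntheticScene:
    """Generate a landing flight and its noisy two-camera pixel tracks."""
    traj, windows = generate_landing_trajectory(params, seed)
    if cameras is None:
        cameras = make_default_cameras()
    rng = np.random.default_rng(seed + 1_000_003)
    tracks = {}
    for name, cam in zip(("cam1", "cam2"), cameras):
        head, _ = project_to_camera(traj.X, cam, pixel_noise_sd, rng)
        abd, _ = project_to_camera(traj.X_abd, cam, pixel_noise_sd, rng)
        tracks[name] = {"head": head, "abd": abd}
    return SyntheticScene(
        ground_truth=traj,
        annotations=windows,
        tracks=tracks,
        cameras=cameras,
        design_row=dict(design_row or {}),
    )


# ---------------------------------------------------------------------------
# study designs

#: white-condition baselines of the per-phase metrics (natural units)
BASELINES = {
    ("dt", "TL"): 1.27,
    ("dt", "LE"): 0.19,
    ("T", "TL"): 4.18,
    ("T", "LE"): 1.47,
    ("U", "TL"): 0.123,
    ("U", "LE"): 0.060,
    ("D_E", "TL"): 0.035,
    ("D_E", "LE"): 0.00895,
    ("H", "TL"): -0.00668,
    ("H", "LE"): 0.00078,
    ("B", "TL"): 37.4,
    ("B", "LE"): 42.2,
}

#: red-blue vs white multiplicative effects for positive (log-scale) metrics
DEFAULT_MULTIPLIERS = {
    ("dt", "TL"): 1.10 / 1.27,
    ("dt", "LE"): 0.24 / 0.19,
    ("T", "TL"): 3.21 / 4.18,
    ("T", "LE"): 1.68 / 1.47,
    ("U", "TL"): 0.105 / 0.123,
    ("U", "LE"): 0.057 / 0.060,
    ("D_E", "TL"): 1.0,
    ("D_E", "LE"): 9.37 / 8.95,
}

#: red-blue vs white additive effects for sign-indefinite metrics
DEFAULT_OFFSETS = {
    ("H", "TL"): 0.00039,
    ("H", "LE"): -0.00134,
    ("B", "TL"): 0.3,
    ("B", "LE"): -0.8,
}

#: residual standard deviations of the additive (natural-scale) metrics
ADDITIVE_RESIDUAL_SD = {"H": 0.003, "B": 5.0}


@dataclass(frozen=True)
class StudyDesign:
    """Two-condition landing study with day-level random intercepts.

    Defaults are the recorded cohort: 44 white and 61 red-blue landings over
    8 days, multiplicative condition effects on positive metrics (log-scale
    additive) and additive effects on height and pitch. ``day_sd`` and
    ``residual_sd`` act on the log scale for log-normal metrics.
    """

    n_white: int = 44
    n_red_blue: int = 61
    n_days: int = 8
    day_sd: float = 0.10
    residual_sd: float = 0.40
    condition_multipliers: dict = field(default_factory=lambda: dict(DEFAULT_MULTIPLIERS))
    condition_offsets: dict = field(default_factory=lambda: dict(DEFAULT_OFFSETS))
    baselines: dict = field(default_factory=lambda: dict(BASELINES))
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_white, self.n_red_blue, self.n_days) < 1:
            raise ValueError("counts must be >= 1")
        if self.day_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if any(m <= 0 for m in self.condition_multipliers.values()):
            raise ValueError("multipliers must be positive")


@dataclass
class StudyDataset:
    """Output of :func:`generate_study_dataset`."""

    landings: pd.DataFrame
    metric_table: pd.DataFrame
    design: StudyDesign

    def build_scene(self, landing_id: int, pixel_noise_sd: float = 0.5) -> SyntheticScene:
        row = self.landings.loc[self.landings.landing_id == landing_id].iloc[0]
        params = FlightParams(
            approach_speed=row.approach_speed,
            hover_times=(row.hover_time,),
            le_distance=row.le_distance,
            tortuosity_gain=row.tortuosity_gain,
            pitch_mean=row.pitch_mean,
        )
        return generate_scene(
            params,
            seed=int(row.scene_seed),
            pixel_noise_sd=pixel_noise_sd,
            design_row=row.to_dict(),
        )


def generate_study_dataset(design: StudyDesign, seed: int | None = None) -> StudyDataset:
    """Realise a study: per-landing flight parameters and per-phase metrics.

    Metric values follow the effect model of the statistical stage: for
    positive metrics ``log(value) = log(baseline) + log(multiplier)*rb +
    day_intercept + residual`` with the day intercept drawn once per day and
    shared by all landings of that day; height and pitch take additive
    effects on the natural scale. Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n = design.n_white + design.n_red_blue
    condition = np.array(["white"] * design.n_white + ["red_blue"] * design.n_red_blue)
    day = rng.integers(1, design.n_days + 1, size=n)
    part_of_day = rng.choice(["morning", "afternoon"], size=n)
    day_eff = rng.normal(0.0, design.day_sd, size=design.n_days + 1)
    day_eff_add = rng.normal(0.0, design.day_sd, size=design.n_days + 1)

    landings = pd.DataFrame(
        {
            "landing_id": np.arange(n),
            "condition": condition,
            "day": day,
            "part_of_day": part_of_day,
            "approach_speed": rng.normal(0.12, 0.015, size=n).clip(0.06),
            "hover_time": rng.uniform(0.8, 1.6, size=n),
            "le_distance": rng.normal(0.009, 0.001, size=n).clip(0.005),
            "tortuosity_gain": rng.uniform(0.2, 0.7, size=n),
            "pitch_mean": rng.normal(40.0, 4.0, size=n),
            "scene_seed": rng.integers(0, 2**31 - 1, size=n),
        }
    )

    rb = (condition == "red_blue").astype(float)
    rows = []
    for (metric, phase), baseline in design.baselines.items():
        if (metric, phase) in design.condition_multipliers:
            mult = design.condition_multipliers[(metric, phase)]
            eps = rng.normal(0.0, design.residual_sd, size=n)
            value = np.exp(np.log(baseline) + np.log(mult) * rb + day_eff[day] + eps)
        else:
            off = design.condition_offsets.get((metric, phase), 0.0)
            sd = ADDITIVE_RESIDUAL_SD.get(metric, 1.0)
            eps = rng.normal(0.0, sd, size=n)
            # day effect rescaled to the metric's natural units, keeping the
            # day-to-residual variance ratio of the log-scale metrics
            day_scale = sd * design.day_sd / max(design.residual_sd, 1e-12)
            z_day = day_eff_add[day] / max(design.day_sd, 1e-12) if design.day_sd > 0 else 0.0
            value = baseline + off * rb + day_scale * z_day + eps
        rows.append(
            pd.DataFrame(
                {
                    "landing_id": np.arange(n),
                    "condition": condition,
                    "day": day,
                    "part_of_day": part_of_day,
                    "phase": phase,
                    "metric": metric,
                    "value": value,
                }
            )
        )
    metric_table = pd.concat(rows, ignore_index=True)
    return StudyDataset(landings=landings, metric_table=metric_table, design=design)


def null_design(**kwargs) -> StudyDesign:
    """A design with every condition effect switched off (type-I error runs)."""
    design = StudyDesign(**kwargs)
    return replace(
        design,
        condition_multipliers={k: 1.0 for k in design.condition_multipliers},
        condition_offsets={k: 0.0 for k in design.condition_offsets},
    )


# ---------------------------------------------------------------------------
# lamp spectra


def generate_spectra(
    kind: str,
    grid: np.ndarray | None = None,
    line_positions: tuple[float, ...] = (),
    line_width: float = 2.0,
) -> Spectrum:
    """Synthetic lamp emission spectra (relative photon radiance).

    ``white_broad`` is a smooth broad-spectrum white LED curve across
    400-700 nm; ``red_blue`` concentrates its radiance in narrow peaks at
    455 and 660 nm; ``flat`` is constant; ``lines`` places unit-area
    near-delta peaks at ``line_positions``.
    """
    if grid is None:
        grid = np.arange(350.0, 751.0, 1.0)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("wavelength grid must be strictly increasing")
    def _white(g: np.ndarray) -> np.ndarray:
        return 0.6 * np.exp(-((g - 450.0) ** 2) / (2 * 12.0**2)) + np.exp(
            -((g - 560.0) ** 2) / (2 * 60.0**2)
        )

    if kind == "flat":
        radiance = np.ones_like(grid)
    elif kind == "white_broad":
        radiance = _white(grid)
    elif kind == "red_blue":
        radiance = 0.45 * np.exp(-((grid - 455.0) ** 2) / (2 * 8.0**2)) + np.exp(
            -((grid - 660.0) ** 2) / (2 * 8.0**2)
        )
        # scale so the white:red-blue photon-radiance ratio equals the
        # measured study condition (white 1.35x brighter)
        radiance = radiance * (
            np.trapezoid(_white(grid), grid) / (1.35 * np.trapezoid(radiance, grid))
        )
    elif kind == "lines":
        if not line_positions:
            raise ValueError("kind='lines' needs line_positions")
        radiance = np.zeros_like(grid)
        for pos in line_positions:
            g = np.exp(-((grid - pos) ** 2) / (2 * line_width**2))
            area = np.trapezoid(g, grid)
            radiance = radiance + g / area
    else:
        raise ValueError(f"unknown spectrum kind {kind!r}")
    return Spectrum(wavelength=grid, values=radiance)
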