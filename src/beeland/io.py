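"""Readers and writers for all interchange files.

All interchange is plain CSV/JSON (full float precision, lossless round
trips) plus optional ingestion of a MATLAB container with pre-smoothed
trajectories and flight variables. Frame indices are 0-based, times in
seconds, positions in metres.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import CameraModel
from .kinematics import KinematicSeries
from .segmentation import LandingAnnotation, PhaseWindows, SpeedThresholdModel
from .smoothing import Trajectory3D
from .spectral import Spectrum

FLOAT_FMT = "%.17g"


class SchemaMismatchError(KeyError):
    """A container file lacks expected variables."""


# ---------------------------------------------------------------------------
# CSV contracts


def write_tracks_csv(path, uv_head: np.ndarray, uv_abd: np.ndarray) -> None:
    df = pd.DataFrame(
        {
            "frame": np.arange(len(uv_head)),
            "u_head": uv_head[:, 0],
            "v_head": uv_head[:, 1],
            "u_abd": uv_abd[:, 0],
            "v_abd": uv_abd[:, 1],
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_tracks_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, float_precision="round_trip")
    return (
        df[["u_head", "v_head"]].to_numpy(float),
        df[["u_abd", "v_abd"]].to_numpy(float),
    )


def write_rig_csv(path, world: np.ndarray, uv1: np.ndarray, uv2: np.ndarray) -> None:
    df = pd.DataFrame(
        {
            "id": np.arange(len(world)),
            "x": world[:, 0],
            "y": world[:, 1],
            "z": world[:, 2],
            "u1": uv1[:, 0],
            "v1": uv1[:, 1],
            "u2": uv2[:, 0],
            "v2": uv2[:, 1],
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_rig_csv(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path, float_precision="round_trip")
    return (
        df[["x", "y", "z"]].to_numpy(float),
        df[["u1", "v1"]].to_numpy(float),
        df[["u2", "v2"]].to_numpy(float),
    )


def write_annotations_csv(path, annotations: list[LandingAnnotation]) -> None:
    df = pd.DataFrame(
        [
            {
                "landing_id": a.landing_id,
                "le_frame": a.le_frame,
                "td_frame": a.td_frame,
                "condition": a.condition,
                "day": a.day,
                "part_of_day": a.part_of_day,
                "failed_landing": int(a.failed_landing),
            }
            for a in annotations
        ]
    )
    df.to_csv(path, index=False)


def read_annotations_csv(path) -> list[LandingAnnotation]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        LandingAnnotation(
            landing_id=int(r.landing_id),
            le_frame=int(r.le_frame),
            td_frame=int(r.td_frame),
            condition=str(r.condition),
            day=int(r.day),
            part_of_day=str(r.part_of_day),
            failed_landing=bool(r.failed_landing),
        )
        for r in df.itertuples()
    ]


def write_trajectory_csv(path, traj: Trajectory3D) -> None:
    cols = {
        "frame": np.arange(traj.n_frames),
        "t": traj.t,
        "x": traj.X[:, 0],
        "y": traj.X[:, 1],
        "z": traj.X[:, 2],
        "vx": traj.U[:, 0],
        "vy": traj.U[:, 1],
        "vz": traj.U[:, 2],
        "ax": traj.A[:, 0],
        "ay": traj.A[:, 1],
        "az": traj.A[:, 2],
    }
    if traj.X_abd is not None:
        cols.update(
            x_abd=traj.X_abd[:, 0], y_abd=traj.X_abd[:, 1], z_abd=traj.X_abd[:, 2]
        )
    pd.DataFrame(cols).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_trajectory_csv(path, aligned: bool = False) -> Trajectory3D:
    df = pd.read_csv(path, float_precision="round_trip")
    X_abd = None
    if "x_abd" in df.columns:
        X_abd = df[["x_abd", "y_abd", "z_abd"]].to_numpy(float)
    return Trajectory3D(
        t=df["t"].to_numpy(float),
        X=df[["x", "y", "z"]].to_numpy(float),
        U=df[["vx", "vy", "vz"]].to_numpy(float),
        A=df[["ax", "ay", "az"]].to_numpy(float),
        X_abd=X_abd,
        aligned=aligned,
    )


def write_kinematics_csv(path, kin: KinematicSeries) -> None:
    cols = {
        "frame": np.arange(kin.n_frames),
        "t": kin.t,
        "d_E": kin.d_E,
        "h": kin.h,
        "speed": kin.speed,
        "U_P": kin.U_P,
        "d": kin.d,
        "tau": kin.tau,
    }
    if kin.beta is not None:
        cols["beta"] = kin.beta
    pd.DataFrame(cols).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_kinematics_csv(path) -> KinematicSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    return KinematicSeries(
        t=df["t"].to_numpy(float),
        d_E=df["d_E"].to_numpy(float),
        h=df["h"].to_numpy(float),
        speed=df["speed"].to_numpy(float),
        U_P=df["U_P"].to_numpy(float),
        d=df["d"].to_numpy(float),
        tau=df["tau"].to_numpy(float),
        beta=df["beta"].to_numpy(float) if "beta" in df.columns else None,
    )


def write_phases_csv(path, windows: list[PhaseWindows], landing_ids=None) -> None:
    if landing_ids is None:
        landing_ids = range(len(windows))
    df = pd.DataFrame(
        [
            {
                "landing_id": lid,
                "tl_start_frame": -1 if w.tl_start_frame is None else w.tl_start_frame,
                "le_start_frame": -1 if w.le_start_frame is None else w.le_start_frame,
                "touchdown_frame": w.touchdown_frame,
                "tl_valid": int(w.tl_valid),
                "le_valid": int(w.le_valid),
                "tl_reason": w.tl_reason,
                "le_reason": w.le_reason,
            }
            for lid, w in zip(landing_ids, windows)
        ]
    )
    df.to_csv(path, index=False)


def write_spectrum_csv(path, spec: Spectrum, value_name: str = "radiance") -> None:
    pd.DataFrame({"wavelength_nm": spec.wavelength, value_name: spec.values}).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_spectrum_csv(path) -> Spectrum:
    df = pd.read_csv(path, float_precision="round_trip")
    value_col = [c for c in df.columns if c != "wavelength_nm"][0]
    return Spectrum(df["wavelength_nm"].to_numpy(float), df[value_col].to_numpy(float))


# ---------------------------------------------------------------------------
# JSON contracts


def write_cameras_json(path, cam1: CameraModel, cam2: CameraModel) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "cam1": {"dlt": cam1.dlt.tolist(), "image_size": list(cam1.image_size)},
                "cam2": {"dlt": cam2.dlt.tolist(), "image_size": list(cam2.image_size)},
            },
            indent=2,
        )
    )


def read_cameras_json(path) -> tuple[CameraModel, CameraModel]:
    d = json.loads(Path(path).read_text())
    return tuple(
        CameraModel(dlt=np.asarray(d[k]["dlt"]), image_size=tuple(d[k]["image_size"]))
        for k in ("cam1", "cam2")
    )


def write_threshold_json(path, model: SpeedThresholdModel) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2))


def read_threshold_json(path) -> SpeedThresholdModel:
    return SpeedThresholdModel.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# MATLAB trajectory container ("Dataset 1"-style)

#: default variable-name schema of the container; configuration-driven so a
#: container with different internal names can be mapped without code changes
DATASET1_SCHEMA = {
    "head_position": "X_head",
    "head_velocity": "U_head",
    "abdomen_position": "X_abd",
    "time": "t",
    "flight_variables": "flight_vars",
    "flight_variable_names": "flight_var_names",
}


def write_dataset1(path, trajectories: list[Trajectory3D], flight_vars: pd.DataFrame) -> None:
    """Write a MAT container of pre-smoothed trajectories + flight variables."""
    from scipy.io import savemat

    cell = {
        "X_head": np.empty(len(trajectories), dtype=object),
        "U_head": np.empty(len(trajectories), dtype=object),
        "X_abd": np.empty(len(trajectories), dtype=object),
        "t": np.empty(len(trajectories), dtype=object),
    }
    for i, tr in enumerate(trajectories):
        cell["X_head"][i] = tr.X
        cell["U_head"][i] = tr.U
        cell["X_abd"][i] = tr.X_abd if tr.X_abd is not None else np.zeros_like(tr.X)
        cell["t"][i] = tr.t
    savemat(
        path,
        {
            **cell,
            "flight_vars": flight_vars.to_numpy(float),
            "flight_var_names": np.array(list(flight_vars.columns), dtype=object),
        },
    )


def _load_mat(path) -> dict:
    from scipy.io import loadmat

    try:
        return loadmat(path, squeeze_me=True, struct_as_record=False)
    except NotImplementedError:  # MAT v7.3 is an HDF5 file
        import h5py

        out = {}
        with h5py.File(path, "r") as f:
            for k in f.keys():
                out[k] = np.asarray(f[k])
        return out


def read_dataset1(
    path, schema: dict | None = None
) -> tuple[list[Trajectory3D], pd.DataFrame, dict]:
    """Read a MAT container of Kalman-filtered trajectories + flight variables.

    Trajectories are marked pre-smoothed (the smoothing stage is skipped for
    them). Units are auto-detected: positions whose typical magnitude
    exceeds 1 are taken as millimetres and converted to metres. Returns
    ``(trajectories, flight_variable_table, info)``.
    """
    schema = {**DATASET1_SCHEMA, **(schema or {})}
    raw = _load_mat(path)
    missing = [v for k, v in schema.items() if k != "flight_variable_names" and v not in raw]
    if missing:
        found = sorted(k for k in raw if not k.startswith("__"))
        raise SchemaMismatchError(
            f"container lacks variables {missing}; found {found}"
        )

    def _as_list(obj):
        arr = np.asarray(obj)
        if arr.dtype == object:
            return [np.atleast_2d(np.asarray(a, dtype=float)) for a in arr.ravel()]
        return [np.atleast_2d(arr.astype(float))]

    Xs = _as_list(raw[schema["head_position"]])
    Us = _as_list(raw[schema["head_velocity"]])
    Xas = _as_list(raw[schema["abdomen_position"]])
    ts = [np.asarray(a, dtype=float).ravel() for a in np.asarray(raw[schema["time"]]).ravel()] if np.asarray(raw[schema["time"]]).dtype == object else [np.asarray(raw[schema["time"]], dtype=float).ravel()]

    typical = np.median([np.median(np.abs(X)) for X in Xs if X.size])
    unit = "mm" if typical > 1.0 else "m"
    scale = 1e-3 if unit == "mm" else 1.0

    trajectories = []
    for X, U, Xa, t in zip(Xs, Us, Xas, ts):
        X, U, Xa = X * scale, U * scale, Xa * scale
        A = np.gradient(U, t, axis=0) if len(t) > 2 else np.zeros_like(U)
        trajectories.append(
            Trajectory3D(
                t=t,
                X=X,
                U=U,
                A=A,
                X_abd=Xa,
                aligned=bool(np.allclose(X[-1], 0, atol=1e-9) and abs(t[-1]) < 1e-9),
                meta={"pre_smoothed": True, "unit_detected": unit},
            )
        )
    fv_arr = np.asarray(raw[schema["flight_variables"]], dtype=float)
    names_key = schema["flight_variable_names"]
    if names_key in raw:
        names = [str(s) for s in np.asarray(raw[names_key]).ravel()]
        if fv_arr.ndim == 1:
            fv_arr = fv_arr.reshape(-1, 1) if len(names) == 1 else fv_arr.reshape(1, -1)
        elif fv_arr.shape[1] != len(names) and fv_arr.shape[0] == len(names):
            fv_arr = fv_arr.T
    else:
        fv_arr = np.atleast_2d(fv_arr)
        names = [f"var{i}" for i in range(fv_arr.shape[1])]
    fv = pd.DataFrame(fv_arr, columns=names)
    return trajectories, fv, {"unit_detected": unit, "n_trajectories": len(trajectories)}
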