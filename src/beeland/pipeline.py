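"""End-to-end orchestration: simulate -> calibrate -> reconstruct -> smooth ->
segment -> metrics -> stats -> spectra.

A scene directory holds ``rig.csv``, ``annotations.csv`` and per-landing
two-camera track CSVs under ``tracks/``; :func:`run_pipeline` executes every
applicable stage on such a directory, writes all stage outputs plus a
resolved-config echo and a run log of per-landing exclusions, and returns
the collected results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .config import PipelineConfig
from .geometry import CameraModel, calibrate_dlt, triangulate_track, RigCorrespondences
from .kinematics import KinematicSeries, align_to_touchdown, compute_kinematics
from .metrics import metrics_table
from .segmentation import (
    LandingAnnotation,
    PhaseWindows,
    SpeedThresholdModel,
    fit_speed_threshold,
    segment_batch,
)
from .smoothing import smooth_trajectory
from .stats import run_stats
from .synthetic import (
    StudyDesign,
    SyntheticScene,
    generate_calibration_rig,
    generate_spectra,
    generate_study_dataset,
    project_to_camera,
)

log = logging.getLogger("beeland")


@dataclass
class PipelineResult:
    kinematics: list[KinematicSeries]
    windows: list[PhaseWindows]
    annotations: list[LandingAnnotation]
    threshold_model: SpeedThresholdModel | None
    threshold: float
    metric_table: pd.DataFrame
    stats: pd.DataFrame | None
    exclusions: dict = field(default_factory=dict)


def reconstruct_scene(
    uv_head1: np.ndarray,
    uv_abd1: np.ndarray,
    uv_head2: np.ndarray,
    uv_abd2: np.ndarray,
    cam1: CameraModel,
    cam2: CameraModel,
    config: PipelineConfig,
    td_frame: int,
):
    """Triangulate, smooth and touchdown-align one landing's tracks."""
    head, _, _ = triangulate_track(cam1, cam2, uv_head1, uv_head2)
    abd, _, _ = triangulate_track(cam1, cam2, uv_abd1, uv_abd2)
    spec = config.smoother_spec()
    traj = smooth_trajectory(head, spec, raw_abdomen=abd)
    return align_to_touchdown(traj, td_frame)


def process_synthetic_scene(scene: SyntheticScene, config: PipelineConfig):
    """Full reconstruction of one in-memory synthetic scene."""
    tr1, tr2 = scene.tracks["cam1"], scene.tracks["cam2"]
    traj = reconstruct_scene(
        tr1["head"], tr1["abd"], tr2["head"], tr2["abd"],
        scene.cameras[0], scene.cameras[1],
        config, scene.annotations.touchdown_frame,
    )
    return traj, compute_kinematics(traj)


def pooled_threshold(
    kins: list[KinematicSeries], config: PipelineConfig
) -> tuple[float, SpeedThresholdModel | None]:
    """Resolve the hover threshold: fixed from config, or fitted from pooled U_P.

    When the pooled sample is too small or degenerate for the histogram fit
    (small batches), the canonical threshold of the full study is used and a
    warning logged.
    """
    if config.fixed_threshold is not None:
        return config.fixed_threshold, None
    from .segmentation import DEFAULT_SPEED_THRESHOLD, NoThresholdError, ThresholdFitError

    pooled = np.concatenate([k.U_P for k in kins])
    try:
        model = fit_speed_threshold(pooled)
    except (ValueError, ThresholdFitError, NoThresholdError) as exc:
        log.warning(
            "pooled threshold fit unavailable (%s); falling back to %.3f m/s",
            exc,
            DEFAULT_SPEED_THRESHOLD,
        )
        return DEFAULT_SPEED_THRESHOLD, None
    return model.threshold, model


def analyse(
    kins: list[KinematicSeries],
    annotations: list[LandingAnnotation],
    config: PipelineConfig,
) -> PipelineResult:
    """Segmentation, metrics and statistics on reconstructed kinematics."""
    threshold, model = pooled_threshold(kins, config)
    windows, summary = segment_batch(kins, annotations, threshold)
    table = metrics_table(kins, windows, annotations)
    stats = None
    conditions = {a.condition for a in annotations}
    if {"white", "red_blue"} <= conditions and not table.empty:
        stats = run_stats(table, transform=config.stats_transform)
    for w, a in zip(windows, annotations):
        if not w.tl_valid:
            log.info("landing %s: TL excluded (%s)", a.landing_id, w.tl_reason)
        if not w.le_valid:
            log.info("landing %s: LE excluded (%s)", a.landing_id, w.le_reason)
    return PipelineResult(
        kinematics=kins,
        windows=windows,
        annotations=annotations,
        threshold_model=model,
        threshold=threshold,
        metric_table=table,
        stats=stats,
        exclusions=summary,
    )


# ---------------------------------------------------------------------------
# scene directories


def simulate_to_dir(
    out_dir,
    design: StudyDesign | None = None,
    config: PipelineConfig | None = None,
    n_landings: int | None = None,
) -> Path:
    """Generate a synthetic study and serialise it as a scene directory."""
    out = Path(out_dir)
    (out / "tracks").mkdir(parents=True, exist_ok=True)
    config = config or PipelineConfig()
    design = design or StudyDesign(seed=config.seed)
    dataset = generate_study_dataset(design)
    landings = dataset.landings if n_landings is None else dataset.landings.head(n_landings)

    rng = np.random.default_rng(design.seed + 17)
    world = generate_calibration_rig(36, extent=0.5, seed=design.seed + 18)
    first_scene = dataset.build_scene(int(landings.landing_id.iloc[0]), config.pixel_noise_sd)
    cam1, cam2 = first_scene.cameras
    uv1, _ = project_to_camera(world, cam1, config.pixel_noise_sd, rng)
    uv2, _ = project_to_camera(world, cam2, config.pixel_noise_sd, rng)
    bio.write_rig_csv(out / "rig.csv", world, uv1, uv2)

    annotations = []
    for lid in landings.landing_id:
        scene = dataset.build_scene(int(lid), config.pixel_noise_sd)
        for name in ("cam1", "cam2"):
            bio.write_tracks_csv(
                out / "tracks" / f"landing_{int(lid):03d}_{name}.csv",
                scene.tracks[name]["head"],
                scene.tracks[name]["abd"],
            )
        row = scene.design_row
        annotations.append(
            LandingAnnotation(
                landing_id=int(lid),
                le_frame=int(scene.annotations.le_start_frame),
                td_frame=int(scene.annotations.touchdown_frame),
                condition=str(row.get("condition", "")),
                day=int(row.get("day", 0)),
                part_of_day=str(row.get("part_of_day", "")),
            )
        )
    bio.write_annotations_csv(out / "annotations.csv", annotations)
    bio.write_spectrum_csv(out / "spectrum_white.csv", generate_spectra("white_broad"))
    bio.write_spectrum_csv(out / "spectrum_red_blue.csv", generate_spectra("red_blue"))
    config.dump(out / "config_resolved.yaml")
    return out


def run_pipeline(input_dir, out_dir, config: PipelineConfig | None = None) -> PipelineResult:
    """Execute all applicable stages on a scene directory, writing outputs."""
    config = config or PipelineConfig()
    inp, out = Path(input_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    world, uv1, uv2 = bio.read_rig_csv(inp / "rig.csv")
    cal1 = calibrate_dlt(RigCorrespondences(world, uv1))
    cal2 = calibrate_dlt(RigCorrespondences(world, uv2))
    bio.write_cameras_json(out / "cameras.json", cal1.camera, cal2.camera)
    log.info("calibration RMSE: %.3f px / %.3f px", cal1.rmse_px, cal2.rmse_px)

    annotations = bio.read_annotations_csv(inp / "annotations.csv")
    kins = []
    for ann in annotations:
        stage = f"reconstruct landing {ann.landing_id}"
        try:
            h1, a1 = bio.read_tracks_csv(inp / "tracks" / f"landing_{ann.landing_id:03d}_cam1.csv")
            h2, a2 = bio.read_tracks_csv(inp / "tracks" / f"landing_{ann.landing_id:03d}_cam2.csv")
            traj = reconstruct_scene(
                h1, a1, h2, a2, cal1.camera, cal2.camera, config, ann.td_frame
            )
            bio.write_trajectory_csv(out / f"traj_{ann.landing_id:03d}.csv", traj)
            kin = compute_kinematics(traj)
            bio.write_kinematics_csv(out / f"kin_{ann.landing_id:03d}.csv", kin)
            kins.append(kin)
        except Exception as exc:
            raise RuntimeError(f"stage failed: {stage}: {exc}") from exc

    result = analyse(kins, annotations, config)
    if result.threshold_model is not None:
        bio.write_threshold_json(out / "threshold.json", result.threshold_model)
    bio.write_phases_csv(
        out / "phases.csv", result.windows, [a.landing_id for a in annotations]
    )
    result.metric_table.to_csv(out / "metrics.csv", index=False)
    if result.stats is not None:
        result.stats.to_csv(out / "stats.csv", index=False)
    config.dump(out / "config_resolved.yaml")
    (out / "run_log.json").write_text(
        json.dumps(
            {
                "threshold": result.threshold,
                "exclusions": result.exclusions,
                "n_landings": len(annotations),
            },
            indent=2,
        )
    )
    return result
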