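import numpy as np
import pytest

from beeland.kinematics import body_pitch_series, compute_kinematics
from beeland.synthetic import (
    FlightParams,
    StudyDesign,
    generate_calibration_rig,
    generate_landing_trajectory,
    generate_scene,
    generate_spectra,
    generate_study_dataset,
    make_default_cameras,
    null_design,
    project_to_camera,
)


class TestLandingTrajectory:
    def test_ends_at_origin_with_negative_time(self):
        tr, win = generate_landing_trajectory(FlightParams(), seed=1)
        assert np.allclose(tr.X[-1], 0.0, atol=1e-12)
        assert tr.t[-1] == 0.0
        assert win.touchdown_frame == tr.n_frames - 1

    def test_leg_extension_distance_within_five_percent(self):
        for seed in range(10):
            p = FlightParams(le_distance=0.009)
            tr, win = generate_landing_trajectory(p, seed=seed)
            d_E = np.linalg.norm(tr.X[win.le_start_frame])
            assert 0.00855 <= d_E <= 0.00945

    def test_hover_reaches_low_speed_at_requested_time(self):
        p = FlightParams(hover_times=(1.0, 1.8), duration=3.0)
        tr, _ = generate_landing_trajectory(p, seed=2)
        kin = compute_kinematics(tr)
        for h in p.hover_times:
            idx = np.argmin(np.abs(tr.t + h))
            window = slice(max(idx - 1, 0), idx + 2)
            assert np.abs(kin.U_P[window]).min() <= p.hover_depth

    def test_zero_gain_gives_straight_line_with_unit_tortuosity(self):
        tr, _ = generate_landing_trajectory(FlightParams(tortuosity_gain=0.0), seed=3)
        # the path is exactly collinear
        dirs = tr.X[:-1] / np.linalg.norm(tr.X[:-1], axis=1, keepdims=True)
        assert np.allclose(dirs, dirs[0], atol=1e-9)
        # tortuosity is 1 up to the central-difference endpoint tolerance
        kin = compute_kinematics(tr)
        assert np.all(np.abs(kin.tau[:-1] - 1.0) < 0.01)

    def test_abdomen_placed_at_pitch_mean(self):
        p = FlightParams(pitch_mean=37.5)
        tr, _ = generate_landing_trajectory(p, seed=4)
        beta = body_pitch_series(tr.X, tr.X_abd)
        assert np.allclose(beta, 37.5, atol=1e-8)
        assert np.allclose(
            np.linalg.norm(tr.X - tr.X_abd, axis=1), p.body_length, atol=1e-12
        )

    def test_duration_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            FlightParams(hover_times=(2.9,), duration=3.0)

    def test_deterministic_under_seed(self):
        a, _ = generate_landing_trajectory(FlightParams(), seed=9)
        b, _ = generate_landing_trajectory(FlightParams(), seed=9)
        assert np.array_equal(a.X, b.X)
        assert np.array_equal(a.U, b.U)


class TestCalibrationRig:
    def test_points_inside_cube_and_non_coplanar(self):
        pts = generate_calibration_rig(36, extent=0.5, seed=1)
        assert pts.shape == (36, 3)
        assert np.all(np.abs(pts) <= 0.25)
        assert np.linalg.matrix_rank(pts - pts.mean(axis=0)) == 3

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            generate_calibration_rig(5)

    def test_six_points_give_full_rank_design(self):
        from beeland.geometry import _design_matrix

        pts = generate_calibration_rig(6, seed=2)
        cam = make_default_cameras()[0]
        uv, _ = cam.project(pts)
        A, _ = _design_matrix(pts, uv)
        assert np.linalg.matrix_rank(A) == 11


class TestProjection:
    def test_axis_point_maps_to_principal_point(self):
        cam = make_default_cameras()[0]  # top camera, optical axis through origin
        uv, valid = cam.project(np.array([0.0, 0.0, 0.1]))
        assert valid[0]
        assert uv[0] == pytest.approx([640.0, 512.0])

    def test_noise_free_projection_exact(self, cameras):
        pts = generate_calibration_rig(50, seed=3)
        uv_a, _ = project_to_camera(pts, cameras[0], pixel_noise_sd=0.0)
        uv_b, _ = cameras[0].project(pts)
        assert np.array_equal(uv_a, uv_b)

    def test_noise_rms_matches_requested_sd(self, cameras):
        pts = generate_calibration_rig(1000, seed=4)
        uv0, _ = cameras[0].project(pts)
        uv, _ = project_to_camera(pts, cameras[0], pixel_noise_sd=0.5, seed=5)
        rms = np.sqrt(np.mean((uv - uv0) ** 2))
        assert 0.45 < rms < 0.55

    def test_principal_plane_point_flagged_invalid(self, cameras):
        cam = cameras[0]
        d = np.array([0.0, 0.0, 1.0])
        denom_grad = cam.dlt[8:11]
        point = -d / (denom_grad @ d)  # DLT denominator exactly zero
        _, valid = cam.project(point)
        assert not valid[0]


class TestStudyDataset:
    def test_same_seed_reproduces_tables_exactly(self):
        a = generate_study_dataset(StudyDesign(seed=5))
        b = generate_study_dataset(StudyDesign(seed=5))
        assert a.landings.equals(b.landings)
        assert a.metric_table.equals(b.metric_table)

    def test_log_mean_difference_matches_multiplier(self):
        design = StudyDesign(
            n_white=4000, n_red_blue=4000, day_sd=0.0, residual_sd=0.2, seed=6
        )
        ds = generate_study_dataset(design)
        sub = ds.metric_table.query("metric == 'dt' and phase == 'LE'")
        diff = (
            np.log(sub[sub.condition == "red_blue"].value).mean()
            - np.log(sub[sub.condition == "white"].value).mean()
        )
        assert diff == pytest.approx(np.log(0.24 / 0.19), abs=0.02)

    def test_null_design_condition_difference_vanishes(self):
        ds = generate_study_dataset(null_design(n_white=4000, n_red_blue=4000, seed=7))
        sub = ds.metric_table.query("metric == 'dt' and phase == 'LE'")
        diff = (
            np.log(sub[sub.condition == "red_blue"].value).mean()
            - np.log(sub[sub.condition == "white"].value).mean()
        )
        assert abs(diff) < 0.05

    def test_day_intercepts_shared_within_day(self):
        """With residual noise off, all same-day landings share the day shift."""
        design = StudyDesign(day_sd=0.3, residual_sd=0.0, seed=8)
        ds = generate_study_dataset(design)
        sub = ds.metric_table.query("metric == 'dt' and phase == 'LE'")
        for (day, cond), grp in sub.groupby(["day", "condition"]):
            assert np.allclose(np.log(grp.value), np.log(grp.value).iloc[0])

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            StudyDesign(n_white=0)
        with pytest.raises(ValueError):
            StudyDesign(day_sd=-0.1)
        with pytest.raises(ValueError):
            StudyDesign(condition_multipliers={("dt", "LE"): -1.0})

    def test_build_scene_round_trip(self):
        ds = generate_study_dataset(StudyDesign(seed=9))
        scene = ds.build_scene(0, pixel_noise_sd=0.0)
        assert scene.tracks["cam1"]["head"].shape == scene.tracks["cam2"]["head"].shape
        assert np.allclose(scene.ground_truth.X[-1], 0.0, atol=1e-12)


class TestSpectra:
    def test_red_blue_concentrated_at_led_peaks(self):
        rb = generate_spectra("red_blue")
        mask = (np.abs(rb.wavelength - 455) <= 30) | (np.abs(rb.wavelength - 660) <= 30)
        frac = np.trapezoid(rb.values * mask, rb.wavelength) / rb.integral()
        assert frac >= 0.99

    def test_flat_constant(self):
        flat = generate_spectra("flat")
        assert np.all(flat.values == flat.values[0])

    def test_lines_have_unit_area(self):
        lines = generate_spectra("lines", line_positions=(540.0,))
        assert lines.integral() == pytest.approx(1.0, rel=1e-6)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            generate_spectra("sunlight")
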