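import numpy as np
import pytest
from scipy import optimize, stats as sps

from beeland.kinematics import KinematicSeries, compute_kinematics
from beeland.segmentation import (
    AnnotationError,
    LandingAnnotation,
    NoThresholdError,
    PhaseWindows,
    detect_tl_start,
    fit_speed_threshold,
    segment_batch,
    segment_landing,
)
from beeland.synthetic import FlightParams, generate_landing_trajectory


def analytic_crossing(w_hover, mu_app, sd_hover, sd_app):
    """Closed-form threshold of a two-Gaussian speed mixture.

    First speed right of the density's global mode at which the density
    returns to its value at zero speed.
    """
    f = lambda x: w_hover * sps.norm.pdf(x, 0, sd_hover) + (1 - w_hover) * sps.norm.pdf(
        x, mu_app, sd_app
    )
    xs = np.linspace(-0.2, 0.6, 40001)
    mode = xs[np.argmax(f(xs))]
    f0 = f(0.0)
    right = xs[xs > mode]
    vals = f(right) - f0
    i = np.where((vals[:-1] > 0) & (vals[1:] <= 0))[0][0]
    return optimize.brentq(lambda x: f(x) - f0, right[i], right[i + 1])


def _mixture(n, w_hover, mu_app, sd_hover, sd_app, seed):
    rng = np.random.default_rng(seed)
    n_h = int(n * w_hover)
    return np.concatenate(
        [rng.normal(0, sd_hover, n_h), rng.normal(mu_app, sd_app, n - n_h)]
    )


def _series_from(d_E, dt=0.01, speed=None):
    from beeland.kinematics import approach_speed_series, tortuosity_series

    d_E = np.asarray(d_E, float)
    n = len(d_E)
    t = dt * (np.arange(n) - (n - 1))
    U_P = approach_speed_series(d_E, dt)
    return KinematicSeries(
        t=t,
        d_E=d_E,
        h=np.zeros(n),
        speed=np.abs(U_P) if speed is None else np.full(n, speed),
        U_P=U_P,
        d=d_E.copy(),
        tau=np.ones(n),
    )


class TestThresholdFit:
    def test_recovers_analytic_crossing(self):
        u = _mixture(100_000, 0.25, 0.15, 0.02, 0.05, seed=42)
        model = fit_speed_threshold(u)
        expected = analytic_crossing(0.25, 0.15, 0.02, 0.05)
        assert abs(model.threshold - expected) / expected < 0.05
        assert model.threshold > model.mode_speed
        assert model.predict(np.array([model.threshold]))[0] == pytest.approx(
            model.f_at_zero, rel=1e-6
        )

    def test_threshold_moves_right_with_mode_separation(self):
        t_near = fit_speed_threshold(_mixture(50_000, 0.25, 0.12, 0.02, 0.04, 1)).threshold
        t_far = fit_speed_threshold(_mixture(50_000, 0.25, 0.25, 0.02, 0.04, 1)).threshold
        assert t_far > t_near

    def test_all_positive_samples_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            fit_speed_threshold(rng.normal(0.4, 0.05, 5000).clip(0.2))

    def test_no_crossing_right_of_mode(self):
        # mode far left of zero: the curve is already below its zero-speed
        # value immediately right of the mode's descending flank crossing at 0
        rng = np.random.default_rng(1)
        u = rng.normal(-0.1, 0.04, 20_000)
        u[:100] = rng.normal(0.05, 0.01, 100)
        with pytest.raises(NoThresholdError):
            fit_speed_threshold(u)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_speed_threshold(np.linspace(-0.1, 0.3, 500))

    def test_roundtrip_serialisation(self):
        from beeland.segmentation import SpeedThresholdModel

        m = fit_speed_threshold(_mixture(20_000, 0.25, 0.15, 0.02, 0.05, 7))
        m2 = SpeedThresholdModel.from_dict(m.to_dict())
        assert m2.threshold == m.threshold
        assert np.array_equal(m2.params, m.params)


class TestDetectTlStart:
    def test_recovers_generated_hover(self):
        for seed in range(10):
            tr, win = generate_landing_trajectory(FlightParams(), seed=seed)
            kin = compute_kinematics(tr)
            detected = detect_tl_start(kin)
            assert detected is not None
            assert abs(detected - win.tl_start_frame) <= 2

    def test_distance_criterion_blocks_far_hover(self):
        # slow approach at 0.2 m from the target only
        d_E = np.concatenate([np.full(100, 0.20), np.linspace(0.20, 0.16, 100)])
        kin = _series_from(d_E)
        assert detect_tl_start(kin) is None

    def test_fast_monotonic_approach_not_found(self):
        d_E = np.linspace(0.5, 0.0, 200)  # 0.25 m/s throughout
        kin = _series_from(d_E)
        assert detect_tl_start(kin) is None

    def test_speed_cap_criterion(self):
        # |U_P| below threshold but total speed high (fast tangential pass)
        d_E = np.full(100, 0.05)
        kin = _series_from(d_E, speed=0.5)
        assert detect_tl_start(kin) is None


class TestSegmentLanding:
    def _landing(self, seed=0, **kw):
        tr, win = generate_landing_trajectory(FlightParams(**kw), seed=seed)
        return compute_kinematics(tr), win

    def test_well_formed_landing_valid_and_ordered(self):
        kin, win = self._landing()
        ann = LandingAnnotation(0, win.le_start_frame, win.touchdown_frame)
        seg = segment_landing(kin, ann)
        assert seg.tl_valid and seg.le_valid
        assert seg.tl_start_frame <= seg.le_start_frame <= seg.touchdown_frame
        assert -kin.t[seg.tl_start_frame] > -kin.t[seg.le_start_frame] > 0

    def test_truncated_recording_reported(self):
        # hover happened before the recording: no in-window threshold crossing
        kin, win = self._landing(hover_times=(), final_speed=0.09)
        ann = LandingAnnotation(1, win.le_start_frame, win.touchdown_frame)
        seg = segment_landing(kin, ann)
        assert not seg.tl_valid and seg.tl_reason == "recording_too_short"
        assert seg.le_valid

    def test_le_preceding_tl_invalidates_tl_only(self):
        kin, win = self._landing()
        ann = LandingAnnotation(2, win.tl_start_frame - 40, win.touchdown_frame)
        seg = segment_landing(kin, ann)
        assert not seg.tl_valid and seg.tl_reason == "le_precedes_tl"
        assert seg.le_valid and seg.le_start_frame == win.tl_start_frame - 40

    def test_failed_landing_excludes_both(self):
        kin, win = self._landing()
        ann = LandingAnnotation(3, win.le_start_frame, win.touchdown_frame, failed_landing=True)
        seg = segment_landing(kin, ann)
        assert not seg.tl_valid and not seg.le_valid
        assert seg.tl_reason == seg.le_reason == "failed_landing"

    def test_inconsistent_annotation_rejected(self):
        kin, win = self._landing()
        with pytest.raises(AnnotationError):
            segment_landing(kin, LandingAnnotation(4, win.touchdown_frame + 1, win.touchdown_frame))

    def test_invalid_reason_code_rejected(self):
        with pytest.raises(ValueError):
            PhaseWindows(0, 1, 2, True, True, tl_reason="unknown")


class TestBatch:
    def test_exclusion_bookkeeping(self):
        kins, anns = [], []
        for i in range(20):
            tr, win = generate_landing_trajectory(FlightParams(), seed=i)
            kins.append(compute_kinematics(tr))
            failed = i == 19
            le = win.tl_start_frame - 30 if i == 18 else win.le_start_frame
            anns.append(LandingAnnotation(i, le, win.touchdown_frame, failed_landing=failed))
        windows, summary = segment_batch(kins, anns)
        assert summary["n"] == 20
        assert summary["n_tl_valid"] == 18
        assert summary["n_le_valid"] == 19
        assert summary["le_precedes_tl"] == 1
        assert summary["failed_landing"] == 1
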