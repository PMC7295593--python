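import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from beeland.kinematics import (
    EmptyManoeuvreError,
    align_to_touchdown,
    approach_speed_series,
    body_pitch_series,
    compute_kinematics,
    euclidean_series,
    path_length_series,
    tortuosity_series,
)
from beeland.smoothing import Trajectory3D
from beeland.synthetic import FlightParams, generate_landing_trajectory

from conftest import straight_trajectory


def brute_force_path_to_go(X: np.ndarray) -> np.ndarray:
    """Independent summation oracle for the remaining-path series."""
    n = len(X)
    steps = np.empty(n)
    for i in range(n):
        if i == 0:
            steps[i] = np.linalg.norm(X[1] - X[0])
        elif i == n - 1:
            steps[i] = np.linalg.norm(X[-1] - X[-2])
        else:
            steps[i] = np.linalg.norm(X[i + 1] - X[i - 1]) / 2.0
    return np.array([steps[i + 1 :].sum() for i in range(n)])


class TestAlignment:
    def test_touchdown_is_origin_at_time_zero(self):
        tr, _ = generate_landing_trajectory(FlightParams(), seed=0)
        raw = Trajectory3D(
            t=tr.t + 5.0, X=tr.X + 0.3, U=tr.U, A=tr.A, X_abd=tr.X_abd + 0.3
        )
        aligned = align_to_touchdown(raw, raw.n_frames - 1)
        assert np.allclose(aligned.X[-1], 0.0)
        assert aligned.t[-1] == 0.0
        assert np.all(aligned.t[:-1] < 0)

    def test_frames_after_touchdown_dropped(self):
        tr = straight_trajectory(n=501)
        raw = Trajectory3D(t=tr.t + 10.0, X=tr.X, U=tr.U, A=tr.A)
        aligned = align_to_touchdown(raw, 400)
        assert aligned.n_frames == 401
        assert aligned.t[0] == pytest.approx(-4.0)

    def test_idempotent(self):
        tr = straight_trajectory(n=101)
        twice = align_to_touchdown(tr, tr.n_frames - 1)
        assert np.allclose(twice.X, tr.X)
        assert np.allclose(twice.t, tr.t)

    def test_touchdown_at_frame_zero_rejected(self):
        tr = straight_trajectory(n=101)
        with pytest.raises(EmptyManoeuvreError):
            align_to_touchdown(tr, 0)


class TestPathLength:
    def test_uniform_motion(self):
        tr = straight_trajectory(speed=0.10, n=201)
        d = path_length_series(tr)
        # frame 100 before touchdown at 0.10 m/s, 100 fps
        assert d[100] == pytest.approx(0.100, abs=1e-9)
        assert d[-1] == 0.0
        assert np.all(np.diff(d) <= 1e-15)  # non-increasing toward touchdown

    def test_zigzag_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        n = 150
        t = 0.01 * (np.arange(n) - (n - 1))
        X = np.cumsum(rng.normal(0, 1e-3, (n, 3)), axis=0)
        X -= X[-1]
        tr = Trajectory3D(t=t, X=X, U=np.zeros((n, 3)) + 1e-9, A=np.zeros((n, 3)), aligned=True)
        assert np.allclose(path_length_series(tr), brute_force_path_to_go(X), atol=1e-12)

    def test_too_few_frames_rejected(self):
        tr = straight_trajectory(n=2)
        with pytest.raises(ValueError):
            path_length_series(tr)


class TestTortuosity:
    def test_straight_approach_is_one(self):
        tr = straight_trajectory(speed=0.08, n=301, direction=(-0.6, 0.8, 0.0))
        kin = compute_kinematics(tr)
        assert np.all(np.abs(kin.tau[:-1] - 1.0) < 0.01)

    def test_semicircular_arc_start_is_half_pi(self):
        r = 0.05
        n = 401
        theta = np.linspace(np.pi, 0.0, n)  # half circle ending at origin
        X = np.column_stack([-r + r * np.cos(theta), r * np.sin(theta), np.zeros(n)])
        t = 0.01 * (np.arange(n) - (n - 1))
        tr = Trajectory3D(t=t, X=X, U=np.zeros((n, 3)), A=np.zeros((n, 3)), aligned=True)
        tau = tortuosity_series(path_length_series(tr), euclidean_series(tr))
        assert tau[0] == pytest.approx(np.pi / 2, rel=1e-3)

    def test_equals_oracle_ratio_on_tortuous_track(self):
        tr, _ = generate_landing_trajectory(FlightParams(tortuosity_gain=0.6), seed=5)
        kin = compute_kinematics(tr)
        with np.errstate(invalid="ignore"):
            oracle = brute_force_path_to_go(tr.X) / euclidean_series(tr)
        valid = euclidean_series(tr) > 0
        assert np.allclose(kin.tau[valid], oracle[valid], atol=1e-9)

    def test_touchdown_frame_undefined(self):
        tr = straight_trajectory()
        kin = compute_kinematics(tr)
        assert np.isnan(kin.tau[-1])

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            tortuosity_series(np.array([-1.0, 0.0]), np.array([1.0, 1.0]))


class TestBodyPitch:
    def test_forty_five_degrees(self):
        # z points down: abdomen at z=+0.01 sits below the head
        beta = body_pitch_series(np.zeros((1, 3)), np.array([[-0.01, 0.0, 0.01]]))
        assert beta[0] == pytest.approx(45.0)

    def test_horizontal_body_zero(self):
        beta = body_pitch_series(np.zeros((1, 3)), np.array([[0.02, 0.0, 0.0]]))
        assert beta[0] == pytest.approx(0.0)

    def test_zero_length_body_undefined(self):
        beta = body_pitch_series(np.zeros((1, 3)), np.zeros((1, 3)))
        assert np.isnan(beta[0])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        theta=st.floats(-1.5, 1.5),
        phi=st.floats(0.0, 2 * np.pi),
        length=st.floats(0.005, 0.05),
    )
    def test_matches_rotation_matrix_oracle(self, theta, phi, length):
        """Body vectors built by explicit rotations recover the pitch angle."""
        # independent construction: rotate a horizontal unit vector by pitch
        # theta about the horizontal axis, then by yaw phi about vertical
        body_dir = np.array(
            [np.cos(theta) * np.cos(phi), np.cos(theta) * np.sin(phi), -np.sin(theta)]
        )  # z down: positive pitch tilts the head upward (negative z)
        head = np.array([[0.01, -0.02, 0.003]])
        abdomen = head - length * body_dir
        beta = body_pitch_series(head, abdomen)
        assert beta[0] == pytest.approx(np.degrees(theta), abs=1e-10)


class TestApproachSpeed:
    def test_linear_approach_positive(self):
        tr = straight_trajectory(speed=0.05)
        kin = compute_kinematics(tr)
        assert np.allclose(kin.U_P[1:-1], 0.05, atol=1e-9)

    def test_receding_flight_negative(self):
        d_E = np.linspace(0.0, 0.5, 100)  # moving away
        U_P = approach_speed_series(d_E, 0.01)
        assert np.all(U_P < 0)

    def test_hover_near_zero(self):
        U_P = approach_speed_series(np.full(50, 0.1), 0.01)
        assert np.allclose(U_P, 0.0)


class TestInvariants:
    @pytest.mark.parametrize("gain", [0.0, 0.3, 0.7])
    def test_tau_at_least_one_and_radial_below_total_speed(self, gain):
        tr, _ = generate_landing_trajectory(FlightParams(tortuosity_gain=gain), seed=2)
        kin = compute_kinematics(tr)
        valid = ~np.isnan(kin.tau)
        assert np.all(kin.tau[valid] >= 1.0 - 0.01)
        # radial speed below total speed up to central-difference error
        # (O(dt*|dv/dt|) near the hover dips and the deceleration ramp)
        assert np.all(np.abs(kin.U_P[1:-1]) <= kin.speed[1:-1] + 1e-3)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(angle=st.floats(0.0, 2 * np.pi))
    def test_rigid_rotation_invariance(self, angle):
        """d, d_E, tau are unchanged by horizontal rotation about the origin."""
        tr, _ = generate_landing_trajectory(FlightParams(tortuosity_gain=0.5), seed=3)
        c, s = np.cos(angle), np.sin(angle)
        R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        rot = Trajectory3D(
            t=tr.t, X=tr.X @ R.T, U=tr.U @ R.T, A=tr.A @ R.T, aligned=True
        )
        assert np.allclose(path_length_series(rot), path_length_series(tr), atol=1e-12)
        assert np.allclose(euclidean_series(rot), euclidean_series(tr), atol=1e-12)
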