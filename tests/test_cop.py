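"""COP trajectory estimation and sway-feature math."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from olst import cop
from olst.errors import InsufficientDataError
from olst.records import PressureFrameSeries

from conftest import apen_bruteforce, hull_area_bruteforce


def _series_from_dense(frames, pitch=1.0, fs=20.0):
    """Build a PressureFrameSeries from a list of {(row, col): value}."""
    fi, rr, cc, vv = [], [], [], []
    for i, fr in enumerate(frames):
        for (r, c), v in fr.items():
            fi.append(i); rr.append(r); cc.append(c); vv.append(v)
    return PressureFrameSeries(
        timestamps=np.arange(len(frames)) / fs,
        frame_index=np.array(fi), rows=np.array(rr), cols=np.array(cc),
        values=np.array(vv), grid_shape=(48, 48), cell_pitch=pitch)


class TestCopTrajectory:
    def test_point_mass_constant_cop(self):
        # single active cell: COP pinned at the cell center, zero path
        frames = [{(10, 20): 5.0, (10, 21): 4.0, (11, 20): 3.0}] * 40
        traj = cop.compute_cop_trajectory(_series_from_dense(frames))
        assert traj.valid.all()
        assert np.allclose(traj.points, traj.points[0])
        length, speed = cop.sway_path_metrics(traj)
        assert length == pytest.approx(0.0)
        assert speed == pytest.approx(0.0)

    def test_weighted_centroid(self):
        # cells 4 cm apart with pressures 1:3 -> centroid 3 cm from the lighter
        frames = [{(24, 20): 1.0, (24, 24): 3.0, (25, 22): 1e-9}] * 5
        series = _series_from_dense(frames)
        x, y = series.cell_xy()
        w = series.values[series.frame_index == 0]
        xs = x[series.frame_index == 0]
        cx = (w * xs).sum() / w.sum()
        assert cx - xs.min() == pytest.approx(3.0, abs=1e-6)

    def test_ellipse_alignment_rotates_motion_onto_y(self):
        # centroid tracing a 30-degree line ends up on the Y axis
        rng = np.random.default_rng(0)
        frames = []
        for t in np.linspace(-1, 1, 60):
            r0 = 24 + int(round(8 * t * np.cos(np.radians(60))))
            c0 = 24 + int(round(8 * t * np.cos(np.radians(30))))
            frames.append({(r0 + dr, c0 + dc): 1.0 + 0.01 * rng.random()
                           for dr in (-1, 0, 1) for dc in (-1, 0, 1)})
        traj = cop.compute_cop_trajectory(_series_from_dense(frames))
        x_spread = np.ptp(traj.points[traj.valid, 0])
        y_spread = np.ptp(traj.points[traj.valid, 1])
        assert y_spread > 10 * x_spread
        assert traj.ellipse.major >= traj.ellipse.minor

    def test_all_invalid_raises(self):
        frames = [{(1, 1): 1.0}] * 10   # < 3 active cells everywhere
        with pytest.raises(InsufficientDataError):
            cop.compute_cop_trajectory(_series_from_dense(frames))


class TestPathMetrics:
    def _traj(self, pts, dt=1.0):
        pts = np.asarray(pts, dtype=float)
        return cop.CopTrajectory(
            timestamps=np.arange(len(pts)) * dt, points=pts,
            valid=np.ones(len(pts), dtype=bool),
            ellipse=cop.FootEllipse((0, 0), 1, 1, 0))

    def test_three_four_five(self):
        length, speed = cop.sway_path_metrics(self._traj([(0, 0), (3, 4)]))
        assert length == pytest.approx(5.0)
        assert speed == pytest.approx(5.0)

    def test_unit_square_walk(self):
        length, speed = cop.sway_path_metrics(
            self._traj([(0, 0), (1, 0), (1, 1), (0, 1)]))
        assert length == pytest.approx(3.0)
        assert speed == pytest.approx(1.0)

    def test_speed_times_elapsed_is_length(self):
        rng = np.random.default_rng(3)
        traj = self._traj(rng.normal(size=(25, 2)), dt=0.05)
        length, speed = cop.sway_path_metrics(traj)
        assert speed * (traj.timestamps[-1] - traj.timestamps[0]) == \
            pytest.approx(length, rel=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(30, 2))
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = pts @ R.T + np.array([3.0, -2.0])
        l1, _ = cop.sway_path_metrics(self._traj(pts))
        l2, _ = cop.sway_path_metrics(self._traj(moved))
        assert l1 == pytest.approx(l2, rel=1e-12)
        assert cop.convex_hull_area(pts) == \
            pytest.approx(cop.convex_hull_area(moved), rel=1e-9)

    def test_subsampling_never_lengthens(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(40, 2))
        l_full, _ = cop.sway_path_metrics(self._traj(pts))
        l_half, _ = cop.sway_path_metrics(self._traj(pts[::2]))
        assert l_half <= l_full + 1e-12

    def test_insufficient_points(self):
        with pytest.raises(InsufficientDataError):
            cop.sway_path_metrics(self._traj([(0, 0)]))


class TestApproximateEntropy:
    def test_constant_series_is_zero(self):
        assert cop.approximate_entropy(np.ones(40), m=2, r=0.1) == 0.0

    def test_alternating_matches_oracle(self):
        x = np.array([1.0, 2.0] * 20)
        got = cop.approximate_entropy(x, m=2, r=0.5)
        assert got == pytest.approx(apen_bruteforce(x, 2, 0.5), abs=1e-9)

    def test_oracle_equivalence_on_random_series(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            x = rng.normal(size=40)
            r = 0.2 * x.std()
            assert cop.approximate_entropy(x, 2, r) == \
                pytest.approx(apen_bruteforce(x, 2, r), abs=1e-9)

    def test_noise_more_complex_than_sine(self):
        rng = np.random.default_rng(4)
        noise = rng.normal(size=40)
        t = np.linspace(0, 4 * np.pi, 40)
        sine = np.sin(t) * noise.std() / np.sin(t).std()
        assert cop.approximate_entropy(noise, 2, 0.2 * noise.std()) > \
            cop.approximate_entropy(sine, 2, 0.2 * sine.std())

    def test_too_short_raises(self):
        with pytest.raises(InsufficientDataError):
            cop.approximate_entropy(np.arange(3), m=2, r=0.5)


class TestConvexHull:
    def test_unit_square(self):
        pts = [(0, 0), (1, 0), (1, 1), (0, 1)]
        assert cop.convex_hull_area(np.array(pts)) == pytest.approx(1.0)

    def test_collinear_is_zero(self):
        pts = np.stack([np.arange(5.0), 2 * np.arange(5.0)], axis=1)
        assert cop.convex_hull_area(pts) == 0.0

    def test_oracle_equivalence_random_sets(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            pts = rng.random((50, 2))
            assert cop.convex_hull_area(pts) == \
                pytest.approx(hull_area_bruteforce(pts), abs=1e-9)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_hull_at_most_bounding_box(self, seed):
        pts = np.random.default_rng(seed).random((20, 2))
        bbox = np.ptp(pts[:, 0]) * np.ptp(pts[:, 1])
        assert cop.convex_hull_area(pts) <= bbox + 1e-12

    def test_empty_raises(self):
        with pytest.raises(InsufficientDataError):
            cop.convex_hull_area(np.empty((0, 2)))


class TestComCop:
    def _traj_from_x(self, x, dt=0.05):
        pts = np.stack([x, np.zeros_like(x)], axis=1)
        return cop.CopTrajectory(np.arange(len(x)) * dt, pts,
                                 np.ones(len(x), dtype=bool),
                                 cop.FootEllipse((0, 0), 1, 1, 0))

    def _kp_with_com_x(self, com_x_cm, px_per_cm=3.0):
        """Collapse the whole skeleton onto one moving point so the
        anthropometric COM equals that point."""
        from olst.records import LANDMARK_NAMES, KeypointSeries
        n = len(com_x_cm)
        data = np.zeros((n, len(LANDMARK_NAMES), 3))
        data[:, :, 0] = np.asarray(com_x_cm)[:, None] * px_per_cm
        data[:, :, 1] = 200.0
        data[:, :, 2] = 1.0
        return KeypointSeries(timestamps=np.arange(n) * 0.05, data=data,
                              px_per_cm=px_per_cm)

    def test_constant_offset_gives_zero(self):
        x = np.sin(np.linspace(0, 6, 80))
        kp = self._kp_with_com_x(x + 7.5)
        assert cop.com_cop_distance(kp, self._traj_from_x(x)) == \
            pytest.approx(0.0, abs=1e-9)

    def test_sine_deviation_mean_two_over_pi(self):
        # COM - COP = sin(t) over whole periods: mean |sin| = 2/pi
        n = 400
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        x = 0.3 * np.cos(3 * t)
        kp = self._kp_with_com_x(x + np.sin(t))
        got = cop.com_cop_distance(kp, self._traj_from_x(x))
        assert got == pytest.approx(2 / np.pi, abs=0.01)

    def test_nonnegative(self, one_trial):
        trial, _ = one_trial
        traj = cop.compute_cop_trajectory(trial.pressure)
        d = cop.com_cop_distance(trial.keypoints, traj, (0.0, 2.0))
        assert d >= 0.0


class TestMaxTrialDuration:
    def test_max_and_ties(self, small_cohort):
        durations = [12.0, 20.0, 8.0, 20.0]
        trials = [type("T", (), {"duration": d})() for d in durations]
        assert cop.max_trial_duration(trials) == 20.0
        assert cop.max_trial_duration(trials[:1]) == 12.0

    def test_empty_raises(self):
        with pytest.raises(InsufficientDataError):
            cop.max_trial_duration([])
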