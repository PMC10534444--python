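"""head_injury: head-center extraction, differentiation, HIC, severity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fallhic as fh
from fallhic.head_injury import G
from fallhic.skeleton_io import HEAD_JOINTS, N_JOINTS


def _pose_from_head(head_traj, fps=120.0):
    """All head joints riding on the given trajectory; body joints below."""
    T = head_traj.shape[0]
    joints = np.zeros((T, N_JOINTS, 3))
    joints[:, :, :] = head_traj[:, None, :]
    body = [j for j in range(N_JOINTS) if j not in HEAD_JOINTS]
    joints[:, body, 2] -= 0.3
    return fh.Pose3DSequence(joints, fps=fps)


class TestHeadCenter:
    def test_identical_head_joints_plus_offset(self):
        traj = np.tile([0.1, 2.0, 0.5], (4, 1))
        pose = _pose_from_head(traj)
        centers, low = fh.head_center(pose, offset=(0.0, 0.0, 0.02))
        assert np.allclose(centers, traj + [0.0, 0.0, 0.02])
        assert not low.any()

    def test_nose_only_available_is_low_confidence(self):
        rng = np.random.default_rng(0)
        joints = rng.normal(0, 0.1, (3, N_JOINTS, 3)) + [0, 2.0, 0.8]
        pose = fh.Pose3DSequence(joints, fps=30.0)
        available = np.zeros((3, N_JOINTS), dtype=bool)
        available[:, 0] = True  # nose only
        centers, low = fh.head_center(pose, available=available)
        assert np.allclose(centers, joints[:, 0, :])
        assert low.all()

    def test_fully_concealed_head_uses_lifted_estimate(self):
        rng = np.random.default_rng(1)
        joints = rng.normal(0, 0.1, (2, N_JOINTS, 3)) + [0, 2.0, 0.8]
        pose = fh.Pose3DSequence(joints, fps=30.0)
        available = np.zeros((2, N_JOINTS), dtype=bool)
        centers, low = fh.head_center(pose, available=available)
        assert np.allclose(centers, joints[:, list(HEAD_JOINTS), :].mean(axis=1))
        assert low.all()

    def test_tracks_simulated_head_center(self, tiny_dataset):
        truth = tiny_dataset.train[0].truth
        centers, _ = fh.head_center(truth.pose3d)
        rms = np.sqrt(((centers - truth.head_center_true) ** 2).sum(axis=1).mean())
        assert rms < 0.02  # within 2 cm of the simulator's head center


class TestDeriveAcceleration:
    def test_free_fall_reads_one_g(self):
        fps = 120.0
        t = np.arange(60) / fps
        traj = np.zeros((60, 3))
        traj[:, 2] = 1.5 - 0.5 * G * t ** 2
        trace = fh.derive_acceleration(traj, fps, smoothing_window=7)
        assert np.allclose(trace.samples[4:-4], 1.0, atol=1e-9)

    def test_stationary_reads_zero(self):
        traj = np.tile([0.3, 2.0, 0.9], (40, 1))
        trace = fh.derive_acceleration(traj, 120.0, smoothing_window=7)
        assert np.allclose(trace.samples, 0.0, atol=1e-9)

    def test_half_sine_pulse_peak_recovered(self):
        """Peak of a simulated soft impact within 5% of the analytic peak."""
        scenario = fh.FallScenario(drop_height=0.3, impact_omega=40.0,
                                   restitution=0.0, fps=240.0)
        truth = fh.simulate_fall(scenario)
        trace = fh.derive_acceleration(truth.head_center_true, 240.0,
                                       smoothing_window=5)
        v = fh.impact_speed(0.3)
        analytic_peak = 0.5 * (1 + scenario.restitution) * v * 40.0 / G
        assert trace.samples.max() == pytest.approx(analytic_peak, rel=0.05)

    def test_too_short_trajectory_rejected(self):
        with pytest.raises(ValueError, match="short"):
            fh.derive_acceleration(np.zeros((5, 3)), 30.0, smoothing_window=7)


class TestComputeHIC:
    def test_zero_trace_gives_zero_with_degenerate_window(self):
        trace = fh.AccelerationTrace(np.zeros(50), fps=1000.0)
        res = fh.compute_hic(trace)
        assert res.hic == 0.0
        assert res.degenerate

    def test_constant_pulse_closed_form(self):
        """a = 100 g for 20 ms at 1 kHz, 15 ms cap: HIC = 0.015 * 100^2.5."""
        trace = fh.AccelerationTrace(np.full(21, 100.0), fps=1000.0)
        res = fh.compute_hic(trace, window_cap=0.015)
        assert res.hic == pytest.approx(0.015 * 100 ** 2.5, rel=1e-12)
        assert res.t2 - res.t1 == pytest.approx(0.015, abs=1e-12)

    def test_matches_bruteforce_on_random_traces(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(10, 120))
            fps = float(rng.uniform(200, 2000))
            a = rng.gamma(2.0, 10.0, n)
            trace = fh.AccelerationTrace(a, fps=fps)
            fast = fh.compute_hic(trace)
            slow = fh.compute_hic_exhaustive(trace)
            assert fast.hic == pytest.approx(slow.hic, rel=1e-9)
            assert (fast.t1, fast.t2) == (slow.t1, slow.t2)

    @given(scale=st.floats(min_value=0.1, max_value=10.0),
           seed=st.integers(min_value=0, max_value=2 ** 16))
    @settings(max_examples=25, deadline=None)
    def test_amplitude_homogeneity_of_degree_2_5(self, scale, seed):
        rng = np.random.default_rng(seed)
        a = rng.gamma(2.0, 20.0, 60)
        base = fh.compute_hic(fh.AccelerationTrace(a, fps=500.0)).hic
        scaled = fh.compute_hic(fh.AccelerationTrace(a * scale, fps=500.0)).hic
        assert scaled == pytest.approx(base * scale ** 2.5, rel=1e-9)

    def test_time_translation_invariance(self):
        a = np.random.default_rng(3).gamma(2.0, 20.0, 80)
        r0 = fh.compute_hic(fh.AccelerationTrace(a, fps=500.0, t0=0.0))
        r1 = fh.compute_hic(fh.AccelerationTrace(a, fps=500.0, t0=2.5))
        assert r1.hic == r0.hic
        assert r1.t1 - r0.t1 == pytest.approx(2.5)

    def test_raising_cap_never_lowers_hic(self):
        a = np.random.default_rng(4).gamma(2.0, 20.0, 200)
        trace = fh.AccelerationTrace(a, fps=1000.0)
        h15 = fh.compute_hic(trace, 0.015).hic
        h36 = fh.compute_hic(trace, 0.036).hic
        assert h36 >= h15

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fh.compute_hic(fh.AccelerationTrace(np.ones(2), fps=100.0))


class TestSeverity:
    @pytest.mark.parametrize("hic, expected", [
        (200.0, fh.SeverityClass.NO_INJURY),
        (800.0, fh.SeverityClass.MODERATE),
        (1500.0, fh.SeverityClass.HEAVY),
    ])
    def test_representative_scores(self, hic, expected):
        assert fh.classify_severity(hic).severity == expected

    @pytest.mark.parametrize("hic, expected", [
        (250.0, fh.SeverityClass.MINOR),
        (700.0, fh.SeverityClass.MODERATE),
        (1000.0, fh.SeverityClass.HEAVY),
    ])
    def test_boundaries_assigned_to_higher_class(self, hic, expected):
        assert fh.classify_severity(hic).severity == expected

    def test_negative_score_rejected(self):
        with pytest.raises(ValueError):
            fh.classify_severity(-1.0)

    def test_scaling_monotonicity_through_the_pipeline(self):
        """classify(compute_hic(c * trace)) is monotone in c."""
        a = np.random.default_rng(5).gamma(2.0, 15.0, 100)
        trace_hics = [
            fh.compute_hic(fh.AccelerationTrace(a * c, fps=1000.0)).hic
            for c in (0.5, 1.0, 2.0, 4.0)
        ]
        severities = [int(fh.classify_severity(h).severity) for h in trace_hics]
        assert severities == sorted(severities)


def test_trace_text_round_trip(tmp_path):
    a = np.random.default_rng(6).gamma(2.0, 10.0, 30)
    trace = fh.AccelerationTrace(a, fps=250.0, t0=0.1)
    path = tmp_path / "trace.txt"
    trace.save(path)
    back = fh.AccelerationTrace.load(path)
    assert np.allclose(back.samples, trace.samples)
    assert back.fps == pytest.approx(trace.fps)
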