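"""synthetic_falls: ballistics, pulse physics, projection, occlusion, datasets."""

import math

import numpy as np
import pytest

import fallhic as fh
from fallhic.head_injury import G
from fallhic.skeleton_io import N_JOINTS


def test_impact_speed_closed_form():
    assert fh.impact_speed(1.0) == pytest.approx(math.sqrt(2 * 9.81), abs=1e-9)
    assert fh.impact_speed(0.0) == 0.0


def test_negligible_drop_is_no_injury():
    scenario = fh.FallScenario(drop_height=1e-9, impact_omega=400.0)
    truth = fh.simulate_fall(scenario)
    # the pulse amplitude scales with impact speed, hence vanishes with height
    v = fh.impact_speed(scenario.drop_height)
    peak_g = 0.5 * (1 + scenario.restitution) * v * scenario.impact_omega / G
    assert peak_g < 0.01
    assert truth.hic_true < 1.0
    assert truth.severity_true.severity == fh.SeverityClass.NO_INJURY


def test_hic_true_is_selfconsistent_with_bruteforce_oracle():
    scenario = fh.FallScenario(drop_height=0.6, impact_omega=400.0, fps=120.0)
    truth = fh.simulate_fall(scenario)
    oracle = fh.compute_hic_exhaustive(truth.head_accel_true)
    assert truth.hic_true == pytest.approx(oracle.hic, rel=1e-6)
    assert fh.classify_severity(truth.hic_true).severity == truth.severity_true.severity


def test_flight_phase_reads_one_g():
    scenario = fh.FallScenario(drop_height=0.8, impact_omega=300.0)
    trace = fh.true_acceleration_trace(scenario)
    t = trace.times
    flight = (t > scenario.pre_roll + 0.01) & (
        t < scenario.pre_roll + fh.impact_speed(0.8) / G - 0.01
    )
    assert np.allclose(trace.samples[flight], 1.0)


def test_first_impact_peak_dominates_bounce_peak():
    scenario = fh.FallScenario(drop_height=0.7, impact_omega=500.0, restitution=0.4)
    trace = fh.true_acceleration_trace(scenario)
    motion_peak = trace.samples.max()
    # after the first pulse ends, the largest remaining excursion is the bounce
    end_first = scenario.pre_roll + fh.impact_speed(0.7) / G + math.pi / 500.0
    after = trace.times > end_first + 1e-3
    assert trace.samples[after].max() < motion_peak


@pytest.mark.parametrize("omega", [150.0, 600.0])
def test_hic_true_monotone_in_drop_height(omega):
    heights = [0.1, 0.3, 0.6, 0.9, 1.2]
    hics = [
        fh.compute_hic(fh.true_acceleration_trace(
            fh.FallScenario(drop_height=h, impact_omega=omega))).hic
        for h in heights
    ]
    assert np.all(np.diff(hics) >= 0)


def test_hic_true_monotone_in_surface_stiffness():
    omegas = [100.0, 300.0, 900.0, 2000.0]
    hics = [
        fh.compute_hic(fh.true_acceleration_trace(
            fh.FallScenario(drop_height=0.8, impact_omega=w))).hic
        for w in omegas
    ]
    assert np.all(np.diff(hics) >= 0)


def test_too_short_duration_is_parameter_error():
    with pytest.raises(fh.ParameterError, match="duration"):
        fh.simulate_fall(fh.FallScenario(drop_height=1.2, duration=0.5))


def test_projection_identities():
    cam = fh.PinholeCamera(focal=800.0, cx=320.0, cy=320.0,
                           subject_depth=3.0, height=0.8)
    # a point on the optical axis projects to the principal point
    joints = np.zeros((1, N_JOINTS, 3))
    joints[:, :, 1] = 3.0
    joints[:, :, 2] = cam.height
    pose = fh.Pose3DSequence(joints, fps=30.0)
    seq = fh.project_to_camera(pose, cam)
    assert np.allclose(seq.coords, [320.0, 320.0])

    # doubling the focal length doubles displacement from the principal point
    joints[:, :, 0] = 0.4
    pose = fh.Pose3DSequence(joints, fps=30.0)
    d1 = fh.project_to_camera(pose, cam).coords[0, 0, 0] - cam.cx
    cam2 = fh.PinholeCamera(focal=1600.0, cx=320.0, cy=320.0,
                            subject_depth=3.0, height=0.8)
    d2 = fh.project_to_camera(pose, cam2).coords[0, 0, 0] - cam.cx
    assert d2 == pytest.approx(2 * d1, rel=1e-12)


def test_projection_matches_independent_implementation():
    """Second, directly coded pinhole model as the oracle."""
    rng = np.random.default_rng(8)
    cam = fh.PinholeCamera(focal=750.0, cx=300.0, cy=280.0,
                           subject_depth=2.5, height=0.9)
    joints = np.stack([
        rng.uniform(-0.5, 0.5, (4, N_JOINTS)),
        rng.uniform(2.0, 3.0, (4, N_JOINTS)),
        rng.uniform(0.0, 1.2, (4, N_JOINTS)),
    ], axis=2)
    seq = fh.project_to_camera(fh.Pose3DSequence(joints, fps=30.0), cam)
    for t in range(4):
        for j in range(N_JOINTS):
            x, y, z = joints[t, j]
            u = cam.focal * x / y + cam.cx
            v = cam.focal * (cam.height - z) / y + cam.cy
            assert seq.coords[t, j, 0] == pytest.approx(u, abs=1e-9)
            assert seq.coords[t, j, 1] == pytest.approx(v, abs=1e-9)


def test_joint_behind_camera_is_geometry_error():
    joints = np.zeros((1, N_JOINTS, 3))
    joints[:, :, 1] = -1.0
    with pytest.raises(fh.GeometryError):
        fh.project_to_camera(fh.Pose3DSequence(joints, fps=30.0),
                             fh.PinholeCamera())


class TestOcclusion:
    def _long_sequence(self):
        scenario = fh.FallScenario(drop_height=0.5, impact_omega=200.0,
                                   duration=3.4, fps=120.0)
        truth = fh.simulate_fall(scenario)
        return fh.project_to_camera(truth.pose3d, scenario.camera)

    def test_zero_rate_is_identity(self, simple_sequence):
        out = fh.apply_occlusion(simple_sequence, 0.0, seed=1)
        assert np.array_equal(out.coords, simple_sequence.coords)
        assert np.all(out.mask == 1)

    def test_empirical_rate_matches_target(self):
        seq = self._long_sequence()  # 408 frames x 25 joints > 10000
        out = fh.apply_occlusion(seq, 0.2, burst_length=5.0, seed=42)
        frac = 1.0 - out.mask.mean()
        assert frac == pytest.approx(0.2, abs=0.02)

    def test_bursts_are_temporally_contiguous(self):
        seq = self._long_sequence()
        out = fh.apply_occlusion(seq, 0.2, burst_length=8.0, seed=3)
        dropped = out.mask == 0
        # mean run length of dropped spans should reflect the burst structure
        runs = []
        for j in range(N_JOINTS):
            col = dropped[:, j].astype(int)
            changes = np.diff(np.concatenate([[0], col, [0]]))
            starts = np.flatnonzero(changes == 1)
            ends = np.flatnonzero(changes == -1)
            runs.extend(ends - starts)
        assert np.mean(runs) > 3.0  # far above the i.i.d. value of ~1.25

    def test_same_seed_reproduces_masks(self, simple_sequence):
        a = fh.apply_occlusion(simple_sequence, 0.3, seed=9)
        b = fh.apply_occlusion(simple_sequence, 0.3, seed=9)
        assert np.array_equal(a.mask, b.mask)
        assert np.array_equal(a.coords, b.coords)

    def test_occluded_joints_are_zeroed(self, simple_sequence):
        out = fh.apply_occlusion(simple_sequence, 0.3, seed=9)
        dropped = out.mask == 0
        assert dropped.any()
        assert np.all(out.conf[dropped] == 0)
        assert np.all(out.coords[dropped] == 0)


class TestMakeDataset:
    @pytest.mark.parametrize("n, expected", [(10, (8, 2))])
    def test_split_ratio_exact(self, n, expected):
        splits = fh.make_dataset(n, seed=0)
        assert (len(splits.train), len(splits.validation)) == expected

    def test_split_ratio_100(self, tiny_dataset):
        splits = fh.make_dataset(10, split=(8, 2), seed=1)
        assert len(splits.train) + len(splits.validation) == 10

    def test_all_severity_classes_populated(self, tiny_dataset):
        labels = [int(c.truth.severity_true.severity)
                  for c in tiny_dataset.train + tiny_dataset.validation]
        counts = np.bincount(labels, minlength=4)
        assert np.all(counts >= 0.1 * len(labels))

    def test_deterministic_given_seed(self):
        a = fh.make_dataset(10, seed=5)
        b = fh.make_dataset(10, seed=5)
        for ca, cb in zip(a.train, b.train):
            assert ca.truth.scenario == cb.truth.scenario
            assert np.array_equal(ca.occluded2d.coords, cb.occluded2d.coords)

    def test_too_few_falls_rejected(self):
        with pytest.raises(ValueError):
            fh.make_dataset(5, seed=0)


def test_export_clip_round_trips_keypoints(tmp_path, tiny_dataset):
    clip = tiny_dataset.train[0]
    fh.export_clip(clip, tmp_path)
    back = fh.read_openpose_sequence(tmp_path, fps=clip.occluded2d.fps,
                                     scale=clip.occluded2d.scale)
    assert np.array_equal(back.coords, clip.occluded2d.coords)
    sidecar = tmp_path / "ground_truth.json"
    assert sidecar.exists()
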