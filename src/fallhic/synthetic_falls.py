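"""Synthetic toddler-fall generator with analytically known head kinematics.

Real home-surveillance fall footage is not redistributable, so every stage
of the pipeline is exercised on simulated falls whose ground truth is known
in closed form.  A fall is modeled as:

* a quiescent pre-roll with the head at rest at ``drop_height`` above the
  impact level;
* free fall (resultant head acceleration 1 g) until the impact speed
  ``v = sqrt(2 g h)`` is reached;
* a half-sine impact deceleration pulse of angular frequency ``omega``
  (a stiffness surrogate: stiffer surfaces give shorter, taller pulses) and
  duration ``pi / omega``.  The pulse peak is ``(1 + e) v omega / 2`` so the
  pulse carries exactly the impulse that reverses the incoming momentum into
  a rebound at restitution ``e``;
* a ballistic bounce and a second, restitution-scaled absorbing pulse
  (the "secondary collision" visible in real fall traces), then rest.

The remaining 24 joints follow the head through a rigid articulated offset
model: a canonical standing toddler skeleton rotates smoothly from upright
to the impact posture as the fall progresses.  The 3D poses are projected
through a pinhole camera into the BODY_25 2D dialect, and burst-structured
occlusion emulates persistent home occluders (furniture edges).

The true head acceleration is the analytic second time-derivative of the
generated trajectory, sampled on a dedicated high-rate grid (``accel_fps``,
default 2000 Hz): impact pulses last O(10 ms) and would alias at camera
frame rates.  ``hic_true`` is the exhaustive windowed HIC of that trace and
``severity_true`` its four-level class, so every clip carries labels that
are exact by construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .skeleton_io import (
    HEAD_JOINTS, N_JOINTS, KeypointSequence, write_openpose_sequence,
)
from .pose_lifting import Pose3DSequence
from .head_injury import (
    G, AccelerationTrace, SeverityClass, SeverityLabel,
    classify_severity, compute_hic,
)


class ParameterError(ValueError):
    """Scenario parameters are inconsistent (e.g. duration too short)."""


class GeometryError(ValueError):
    """Projection geometry is invalid (joint at or behind the camera)."""


@dataclass(frozen=True)
class PinholeCamera:
    """Ideal pinhole camera looking horizontally along the lab +y axis."""

    focal: float = 800.0           # pixels
    cx: float = 320.0
    cy: float = 320.0
    subject_depth: float = 3.0     # meters, nominal subject plane
    height: float = 0.8            # meters, optical-center height

    @property
    def scale(self) -> float:
        """Meters per pixel at the nominal subject depth."""
        return self.subject_depth / self.focal


@dataclass(frozen=True)
class FallScenario:
    """Physical and imaging parameters of one simulated fall."""

    drop_height: float = 0.6        # m, head-center fall distance
    impact_omega: float = 400.0     # 1/s, half-sine pulse angular frequency
    restitution: float = 0.3        # in [0, 1)
    fps: float = 120.0              # camera frames per second
    duration: float = 1.6           # s
    body_scale: float = 0.85        # m, toddler stature
    camera: PinholeCamera = field(default_factory=PinholeCamera)
    occlusion_rate: float = 0.0     # per joint-frame, in [0, 1)
    burst_length: float = 5.0       # frames, mean occlusion burst
    accel_fps: float = 2000.0       # Hz, ground-truth acceleration sampling
    pre_roll: float = 0.3           # s, quiescent lead-in
    fall_direction: str = "backward"  # "backward" | "forward"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.drop_height < 0:
            raise ParameterError("drop_height must be >= 0")
        for name in ("impact_omega", "fps", "duration", "body_scale", "accel_fps"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        if not (0 <= self.restitution < 1):
            raise ParameterError("restitution must lie in [0, 1)")
        if not (0 <= self.occlusion_rate < 1):
            raise ParameterError("occlusion_rate must lie in [0, 1)")
        if self.fall_direction not in ("backward", "forward"):
            raise ParameterError("fall_direction must be 'backward' or 'forward'")


#: Canonical standing BODY_25 skeleton for a 0.85 m toddler, meters.
#: Lab frame: x lateral (right positive), y forward, z up from the floor.
_CANONICAL_POSE = np.array([
    (0.000,  0.040, 0.780),   # 0  Nose
    (0.000,  0.000, 0.700),   # 1  Neck
    (-0.090, 0.000, 0.680),   # 2  RShoulder
    (-0.130, 0.010, 0.550),   # 3  RElbow
    (-0.140, 0.030, 0.430),   # 4  RWrist
    (0.090,  0.000, 0.680),   # 5  LShoulder
    (0.130,  0.010, 0.550),   # 6  LElbow
    (0.140,  0.030, 0.430),   # 7  LWrist
    (0.000,  0.000, 0.450),   # 8  MidHip
    (-0.055, 0.000, 0.450),   # 9  RHip
    (-0.060, 0.010, 0.250),   # 10 RKnee
    (-0.060, 0.000, 0.060),   # 11 RAnkle
    (0.055,  0.000, 0.450),   # 12 LHip
    (0.060,  0.010, 0.250),   # 13 LKnee
    (0.060,  0.000, 0.060),   # 14 LAnkle
    (-0.025, 0.055, 0.800),   # 15 REye
    (0.025,  0.055, 0.800),   # 16 LEye
    (-0.050, 0.015, 0.790),   # 17 REar
    (0.050,  0.015, 0.790),   # 18 LEar
    (0.065,  0.080, 0.015),   # 19 LBigToe
    (0.085,  0.070, 0.015),   # 20 LSmallToe
    (0.060, -0.030, 0.025),   # 21 LHeel
    (-0.065, 0.080, 0.015),   # 22 RBigToe
    (-0.085, 0.070, 0.015),   # 23 RSmallToe
    (-0.060, -0.030, 0.025),  # 24 RHeel
])
_CANONICAL_STATURE = 0.85
#: Head-center rest height at ground contact (head half-width, roughly).
_IMPACT_CLEARANCE = 0.08


@dataclass
class GroundTruthFall:
    """A simulated fall with exact labels."""

    scenario: FallScenario
    pose3d: Pose3DSequence
    head_center_true: np.ndarray          # (T, 3) m at camera fps
    head_accel_true: AccelerationTrace    # g, at accel_fps
    hic_true: float
    severity_true: SeverityLabel


# ---- analytic head motion -----------------------------------------------


class _HeadMotion:
    """Piecewise closed-form head-center height z(t) and |z''(t)|."""

    def __init__(self, sc: FallScenario):
        h = sc.drop_height
        e = sc.restitution
        w = sc.impact_omega
        self.z_impact = _IMPACT_CLEARANCE * sc.body_scale / _CANONICAL_STATURE
        self.z_start = self.z_impact + h
        v = math.sqrt(2.0 * G * h)
        self.impact_speed = v
        t0 = sc.pre_roll
        t_fall = v / G
        T_pulse = math.pi / w
        A1 = 0.5 * (1.0 + e) * v * w   # peak of the first pulse, m/s^2
        A2 = 0.5 * e * v * w           # absorbing second pulse
        t_bounce = 2.0 * e * v / G

        # phase boundaries
        self.t0 = t0
        self.t1 = t0 + t_fall                      # first contact
        self.t2 = self.t1 + T_pulse                # end of first pulse
        self.t3 = self.t2 + (t_bounce if e > 0 else 0.0)
        self.t4 = self.t3 + (T_pulse if e > 0 else 0.0)
        self.A1, self.A2, self.w, self.e, self.v = A1, A2, w, e, v

        # position continuity constants
        self.z_e = self.z_impact - v * T_pulse + (A1 / w) * T_pulse
        if e > 0:
            self.z_rest = self.z_e - e * v * T_pulse + (A2 / w) * T_pulse
        else:
            self.z_rest = self.z_e

        if self.t4 > sc.duration:
            raise ParameterError(
                f"duration {sc.duration:.3f} s too short: the fall (pre-roll, "
                f"descent, impact and bounce) lasts {self.t4:.3f} s"
            )

    def z(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.z_rest)
        m = t < self.t0
        out[m] = self.z_start
        m = (t >= self.t0) & (t < self.t1)
        out[m] = self.z_start - 0.5 * G * (t[m] - self.t0) ** 2
        m = (t >= self.t1) & (t < self.t2)
        tau = t[m] - self.t1
        out[m] = (self.z_impact - self.v * tau
                  + (self.A1 / self.w) * (tau - np.sin(self.w * tau) / self.w))
        if self.e > 0:
            m = (t >= self.t2) & (t < self.t3)
            tau = t[m] - self.t2
            out[m] = self.z_e + self.e * self.v * tau - 0.5 * G * tau ** 2
            m = (t >= self.t3) & (t < self.t4)
            tau = t[m] - self.t3
            out[m] = (self.z_e - self.e * self.v * tau
                      + (self.A2 / self.w) * (tau - np.sin(self.w * tau) / self.w))
        return out

    def accel_g(self, t: np.ndarray) -> np.ndarray:
        """Resultant |z''(t)| in g (the head moves only vertically)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape)
        m = (t >= self.t0) & (t < self.t1)
        out[m] = 1.0
        m = (t >= self.t1) & (t < self.t2)
        out[m] = self.A1 * np.sin(self.w * (t[m] - self.t1)) / G
        if self.e > 0:
            m = (t >= self.t2) & (t < self.t3)
            out[m] = 1.0
            m = (t >= self.t3) & (t < self.t4)
            out[m] = self.A2 * np.sin(self.w * (t[m] - self.t3)) / G
        return out

    def progress(self, t: np.ndarray) -> np.ndarray:
        """Monotone fall progress in [0, 1] driving the body rotation."""
        t = np.asarray(t, dtype=float)
        if self.t1 > self.t0:
            p = np.clip((t - self.t0) / (self.t1 - self.t0), 0.0, 1.0)
        else:
            p = (t >= self.t0).astype(float)
        return p * p * (3.0 - 2.0 * p)  # smoothstep


def impact_speed(drop_height: float) -> float:
    """Closed-form impact speed sqrt(2 g h), m/s."""
    return math.sqrt(2.0 * G * max(drop_height, 0.0))


def true_acceleration_trace(scenario: FallScenario) -> AccelerationTrace:
    """Analytic head acceleration in g on the high-rate grid."""
    motion = _HeadMotion(scenario)
    n = int(round(scenario.duration * scenario.accel_fps))
    t = np.arange(n) / scenario.accel_fps
    return AccelerationTrace(motion.accel_g(t), fps=scenario.accel_fps)


def simulate_fall(scenario: FallScenario) -> GroundTruthFall:
    """Generate one labeled fall (3D poses, true acceleration, true HIC)."""
    motion = _HeadMotion(scenario)
    cam = scenario.camera
    nf = int(round(scenario.duration * scenario.fps))
    t = np.arange(nf) / scenario.fps

    body = _CANONICAL_POSE * (scenario.body_scale / _CANONICAL_STATURE)
    head0 = body[list(HEAD_JOINTS)].mean(axis=0)
    offsets = body - head0  # joint offsets relative to the head center

    head = np.zeros((nf, 3))
    head[:, 1] = cam.subject_depth
    head[:, 2] = motion.z(t)

    sign = 1.0 if scenario.fall_direction == "backward" else -1.0
    theta = (math.pi / 2.0) * motion.progress(t)
    c, s = np.cos(theta), np.sin(theta)
    # rotation about the lab x axis: y' = c*y - s*z, z' = s*y + c*z
    rot = np.zeros((nf, N_JOINTS, 3))
    rot[:, :, 0] = offsets[None, :, 0]
    rot[:, :, 1] = sign * (c[:, None] * (sign * offsets[None, :, 1])
                           - s[:, None] * offsets[None, :, 2])
    rot[:, :, 2] = (s[:, None] * (sign * offsets[None, :, 1])
                    + c[:, None] * offsets[None, :, 2])
    joints = head[:, None, :] + rot

    pose3d = Pose3DSequence(joints, fps=scenario.fps)
    accel = true_acceleration_trace(scenario)
    hic = compute_hic(accel)
    label = classify_severity(hic.hic)
    return GroundTruthFall(scenario, pose3d, head, accel, hic.hic, label)


# ---- camera projection and occlusion ------------------------------------


def project_to_camera(pose3d: Pose3DSequence, camera: PinholeCamera) -> KeypointSequence:
    """Pinhole-project a 3D sequence into pixel keypoints (confidence 1)."""
    joints = pose3d.joints
    depth = joints[:, :, 1]
    if np.any(depth <= 1e-6):
        raise GeometryError("joint at or behind the camera plane")
    u = camera.focal * joints[:, :, 0] / depth + camera.cx
    v = camera.focal * (camera.height - joints[:, :, 2]) / depth + camera.cy
    coords = np.stack([u, v], axis=2)
    T = joints.shape[0]
    conf = np.ones((T, N_JOINTS))
    mask = np.ones((T, N_JOINTS), dtype=np.uint8)
    return KeypointSequence(coords, conf, mask, fps=pose3d.fps, scale=camera.scale)


def apply_occlusion(
    seq: KeypointSequence,
    occlusion_rate: float,
    burst_length: float = 5.0,
    seed: int = 0,
) -> KeypointSequence:
    """Drop joints in temporally contiguous bursts.

    Occlusion follows a two-state Markov chain per joint whose stationary
    occluded fraction equals ``occlusion_rate`` and whose burst lengths are
    geometric with mean ``burst_length`` frames.  Occluded joints get
    coordinates (0, 0), confidence 0 and mask 0 (the estimator's encoding
    of a non-detection).  Deterministic given the seed.
    """
    if not (0 <= occlusion_rate < 1):
        raise ValueError("occlusion_rate must lie in [0, 1)")
    if burst_length < 1:
        raise ValueError("burst_length must be >= 1 frame")
    out = seq.copy()
    if occlusion_rate == 0:
        return out
    rng = np.random.default_rng(seed)
    T = seq.n_frames
    p_end = 1.0 / burst_length
    p_start = occlusion_rate * p_end / (1.0 - occlusion_rate)
    occluded = np.zeros((T, N_JOINTS), dtype=bool)
    state = rng.random(N_JOINTS) < occlusion_rate
    for tt in range(T):
        occluded[tt] = state
        u = rng.random(N_JOINTS)
        state = np.where(state, u >= p_end, u < p_start)
    out.coords[occluded] = 0.0
    out.conf[occluded] = 0.0
    out.mask[occluded] = 0
    return out


# ---- dataset assembly ----------------------------------------------------


@dataclass(frozen=True)
class ScenarioRanges:
    """Sampling ranges for random scenarios.

    Defaults span drop heights from barely-off-the-floor to above-crib
    (0.05-1.2 m) and surface stiffness surrogates from soft mattress-like
    (omega ~ 80 1/s, ~40 ms pulses) to hard-floor-like (omega ~ 2500 1/s,
    ~1 ms pulses); omega is sampled log-uniformly.  Jointly with stratified
    class sampling this populates all four severity classes.
    """

    drop_height: tuple[float, float] = (0.05, 1.2)
    impact_omega: tuple[float, float] = (80.0, 2500.0)
    restitution: tuple[float, float] = (0.1, 0.5)
    fps: float = 120.0
    duration: float = 1.6
    body_scale: float = 0.85
    occlusion_rate: float = 0.2
    burst_length: float = 5.0
    camera: PinholeCamera = field(default_factory=PinholeCamera)


@dataclass
class FallClip:
    """One dataset item: ground truth plus clean and occluded 2D views."""

    truth: GroundTruthFall
    clean2d: KeypointSequence
    occluded2d: KeypointSequence


@dataclass
class DatasetSplits:
    train: list[FallClip]
    validation: list[FallClip]
    test: list[FallClip]


def _sample_scenario(rng: np.random.Generator, ranges: ScenarioRanges) -> FallScenario:
    lo, hi = ranges.impact_omega
    omega = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return FallScenario(
        drop_height=float(rng.uniform(*ranges.drop_height)),
        impact_omega=omega,
        restitution=float(rng.uniform(*ranges.restitution)),
        fps=ranges.fps,
        duration=ranges.duration,
        body_scale=ranges.body_scale,
        camera=ranges.camera,
        occlusion_rate=ranges.occlusion_rate,
        burst_length=ranges.burst_length,
        fall_direction="backward" if rng.random() < 0.5 else "forward",
        seed=int(rng.integers(2 ** 31)),
    )


def _sample_scenario_of_class(
    rng: np.random.Generator,
    ranges: ScenarioRanges,
    target: SeverityClass,
    max_tries: int = 500,
) -> FallScenario:
    """Rejection-sample a scenario whose true severity is ``target``."""
    last = None
    for _ in range(max_tries):
        sc = _sample_scenario(rng, ranges)
        last = sc
        hic = compute_hic(true_acceleration_trace(sc)).hic
        if classify_severity(hic).severity == target:
            return sc
    return last  # pragma: no cover - ranges make every class reachable


def make_dataset(
    n_falls: int,
    scenario_ranges: ScenarioRanges | None = None,
    split: tuple[int, int] = (8, 2),
    seed: int = 0,
    n_test: int = 0,
    stratify: bool = True,
) -> DatasetSplits:
    """Build train/validation(/test) collections of labeled fall clips.

    Scenarios are sampled cycling through the four severity classes
    (rejection sampling on the analytic HIC), so every class is populated;
    clips are shuffled before the train/validation split, which honors the
    given ratio to rounding (8:2 by default).  Deterministic given the seed.
    """
    if n_falls < 10:
        raise ValueError("n_falls must be >= 10")
    rng = np.random.default_rng(seed)

    def build(n: int) -> list[FallClip]:
        clips = []
        for i in range(n):
            if stratify:
                target = SeverityClass(i % 4)
                sc = _sample_scenario_of_class(rng, scenario_ranges or ScenarioRanges(), target)
            else:
                sc = _sample_scenario(rng, scenario_ranges or ScenarioRanges())
            truth = simulate_fall(sc)
            clean = project_to_camera(truth.pose3d, sc.camera)
            occluded = apply_occlusion(clean, sc.occlusion_rate, sc.burst_length, seed=sc.seed)
            clips.append(FallClip(truth, clean, occluded))
        return clips

    clips = build(n_falls)
    order = rng.permutation(n_falls)
    n_train = int(round(n_falls * split[0] / (split[0] + split[1])))
    train = [clips[i] for i in order[:n_train]]
    val = [clips[i] for i in order[n_train:]]
    test = build(n_test) if n_test > 0 else []
    return DatasetSplits(train, val, test)


# ---- export ---------------------------------------------------------------


def export_clip(clip: FallClip, directory: str | Path) -> None:
    """Write a clip as per-frame keypoint JSON plus a ground-truth sidecar."""
    directory = Path(directory)
    write_openpose_sequence(clip.occluded2d, directory)
    truth = clip.truth
    sidecar = {
        "format": "fallhic.ground_truth",
        "version": 1,
        "scenario": {
            "drop_height": truth.scenario.drop_height,
            "impact_omega": truth.scenario.impact_omega,
            "restitution": truth.scenario.restitution,
            "fps": truth.scenario.fps,
            "duration": truth.scenario.duration,
            "occlusion_rate": truth.scenario.occlusion_rate,
            "seed": truth.scenario.seed,
        },
        "pose3d": truth.pose3d.joints.tolist(),
        "hic_true": truth.hic_true,
        "severity_true": int(truth.severity_true.severity),
    }
    (directory / "ground_truth.json").write_text(json.dumps(sidecar))
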