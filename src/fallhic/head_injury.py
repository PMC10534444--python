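"""Head-center acceleration, windowed Head Injury Criterion, severity scale.

The Head Injury Criterion scores a resultant head acceleration history
``a(t)`` (in units of g) by

    HIC = max over (t1, t2) of  (t2 - t1) * [ (1/(t2-t1)) * int_{t1}^{t2} a dt ]^2.5

with the window length ``t2 - t1`` capped at 15 ms (HIC-15, the modern
regulatory convention; a 36 ms cap is also in use and available via the
``window_cap`` argument).  Severity is the standard four-level mapping of
the score: below 250 no injury, 250-700 minor (concussion range), 700-1000
moderate (~5% serious-injury probability), above 1000 heavy (~33% skull
fracture probability).  Scores exactly at a boundary are assigned to the
higher class, which keeps the mapping right-continuous and conservative
for alerting.

Acceleration is derived from the lifted head-center trajectory by local
quadratic least-squares smoothing (Savitzky-Golay) per axis followed by
central second differences; the resultant magnitude is divided by 9.81 to
express it in g.  No gravity subtraction is applied by default (the score
uses the resultant magnitude of the position's second derivative); a flag
is provided for callers who prefer net acceleration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path

import numpy as np
from scipy.signal import savgol_filter

from .skeleton_io import HEAD_JOINTS
from .pose_lifting import Pose3DSequence

#: Standard gravity, m/s^2: the g in which HIC accelerations are expressed.
G = 9.81

DEFAULT_WINDOW_CAP = 0.015  # seconds (HIC-15)


@dataclass
class AccelerationTrace:
    """Uniformly sampled resultant head-center acceleration magnitude in g."""

    samples: np.ndarray
    fps: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not (self.fps > 0 and math.isfinite(self.fps)):
            raise ValueError("fps must be strictly positive")
        if np.any(self.samples < 0) or not np.all(np.isfinite(self.samples)):
            raise ValueError("resultant acceleration magnitudes must be finite and >= 0")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fps

    def save(self, path: str | Path) -> None:
        """Two-column delimited text: time_s, accel_g."""
        np.savetxt(path, np.column_stack([self.times, self.samples]),
                   header="time_s accel_g")

    @classmethod
    def load(cls, path: str | Path) -> "AccelerationTrace":
        data = np.loadtxt(path)
        t, a = data[:, 0], data[:, 1]
        dt = np.diff(t)
        if t.size < 2 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("trace file must be uniformly sampled")
        return cls(a, fps=1.0 / dt[0], t0=float(t[0]))


@dataclass(frozen=True)
class HICResult:
    """A HIC score with its maximizing sample-aligned window."""

    hic: float
    t1: float
    t2: float
    window_cap: float = DEFAULT_WINDOW_CAP
    degenerate: bool = False  # all-zero trace: window is arbitrary

    def __post_init__(self) -> None:
        if self.hic < 0:
            raise ValueError("HIC must be non-negative")
        if not (0 < self.t2 - self.t1 <= self.window_cap * (1 + 1e-9)):
            raise ValueError("window must satisfy 0 < t2 - t1 <= window_cap")


@dataclass(frozen=True)
class SeverityThresholds:
    """HIC boundaries of the four-level severity scale."""

    t_minor: float = 250.0
    t_moderate: float = 700.0
    t_heavy: float = 1000.0

    def __post_init__(self) -> None:
        if not (0 < self.t_minor < self.t_moderate < self.t_heavy):
            raise ValueError("thresholds must be strictly increasing and positive")


class SeverityClass(IntEnum):
    NO_INJURY = 0
    MINOR = 1
    MODERATE = 2
    HEAVY = 3

    def __str__(self) -> str:
        return {
            SeverityClass.NO_INJURY: "No injury",
            SeverityClass.MINOR: "Minor injury",
            SeverityClass.MODERATE: "Moderate injury",
            SeverityClass.HEAVY: "Heavy injury",
        }[self]


@dataclass(frozen=True)
class SeverityLabel:
    """A severity class together with the HIC score that produced it."""

    severity: SeverityClass
    hic: float

    def __str__(self) -> str:
        return f"{self.severity} (HIC {self.hic:.1f})"


# ---- head-center trajectory ---------------------------------------------


def head_center(
    pose3d: Pose3DSequence,
    available: np.ndarray | None = None,
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame head-center position from the head-region joints.

    The center is the mean of the available head joints (nose, eyes, ears)
    plus a fixed anatomical offset toward the cranial centroid (default 0;
    surface keypoints already straddle the head).  ``available`` is an
    optional ``(T, 25)`` boolean mask of which joints were actually observed
    in the source 2D; frames where fewer than two head joints were observed
    fall back to all lifted head joints and are flagged low-confidence.

    Returns ``(positions (T, 3) meters, low_confidence (T,) bool)``.
    """
    if pose3d.n_frames == 0:
        raise ValueError("empty 3D sequence")
    head = pose3d.joints[:, HEAD_JOINTS, :]  # (T, 5, 3)
    T = pose3d.n_frames
    off = np.asarray(offset, dtype=float)
    if available is None:
        return head.mean(axis=1) + off, np.zeros(T, dtype=bool)
    avail = np.asarray(available, dtype=bool)[:, HEAD_JOINTS]  # (T, 5)
    n_avail = avail.sum(axis=1)
    low_conf = n_avail < 2
    weights = np.where(avail, 1.0, 0.0)
    # fully concealed head: keep the lifted estimate (mean of all head joints)
    weights[n_avail == 0] = 1.0
    centers = (head * weights[:, :, None]).sum(axis=1) / weights.sum(axis=1)[:, None]
    return centers + off, low_conf


# ---- acceleration -------------------------------------------------------


#: Default smoothing span in seconds; the window covers a fixed time, not a
#: fixed frame count, so pose jitter (amplified by fps^2 in the second
#: difference) is suppressed consistently across camera rates.  ~30 ms
#: balances jitter suppression against attenuating O(10 ms) impact pulses.
DEFAULT_SMOOTHING_SPAN = 0.03


def smoothing_window_for(fps: float, span: float = DEFAULT_SMOOTHING_SPAN) -> int:
    """Odd window length covering ``span`` seconds at ``fps`` (minimum 5)."""
    w = int(round(span * fps))
    w = max(w, 5)
    return w if w % 2 == 1 else w + 1


def derive_acceleration(
    trajectory: np.ndarray,
    fps: float,
    smoothing_window: int | None = None,
    subtract_gravity: bool = False,
    t0: float = 0.0,
) -> AccelerationTrace:
    """Resultant acceleration magnitude (g) of a 3D position trajectory.

    Each axis is smoothed by a local quadratic least-squares fit over
    ``smoothing_window`` frames (default: a ~30 ms span at the given fps),
    then differentiated twice with central second differences (exact for
    quadratics, hence exact for free fall).  With ``subtract_gravity`` the
    constant 1 g is removed from the vertical axis before taking the
    magnitude.
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.ndim != 2 or traj.shape[1] != 3:
        raise ValueError("trajectory must be (T, 3)")
    if fps <= 0:
        raise ValueError("fps must be strictly positive")
    if smoothing_window is None:
        smoothing_window = smoothing_window_for(fps)
    if smoothing_window % 2 == 0 or smoothing_window < 5:
        raise ValueError("smoothing_window must be odd and >= 5")
    T = traj.shape[0]
    if T < smoothing_window + 2:
        raise ValueError(
            f"trajectory too short: need at least smoothing_window + 2 = "
            f"{smoothing_window + 2} frames, got {T}"
        )
    smooth = savgol_filter(traj, smoothing_window, polyorder=2, axis=0, mode="interp")
    acc = np.empty_like(smooth)
    acc[1:-1] = (smooth[2:] - 2 * smooth[1:-1] + smooth[:-2]) * fps ** 2
    acc[0] = acc[1]
    acc[-1] = acc[-2]
    if subtract_gravity:
        acc[:, 2] += G  # position z is up; free fall has z'' = -g
    mag = np.linalg.norm(acc, axis=1) / G
    return AccelerationTrace(mag, fps=fps, t0=t0)


# ---- HIC ----------------------------------------------------------------


def compute_hic(trace: AccelerationTrace, window_cap: float = DEFAULT_WINDOW_CAP) -> HICResult:
    """Windowed HIC by exhaustive search over all sample-aligned windows.

    The integral is trapezoidal; every window ``(i, j)`` with
    ``0 < (j - i)/fps <= window_cap`` is scored as
    ``dt_w * (I_w / dt_w)^2.5`` and the maximum returned.  The search is
    vectorized over all O(T x W) windows but remains exhaustive: it scores
    exactly the same windows as :func:`compute_hic_exhaustive`.
    """
    a = trace.samples
    n = a.size
    if n < 3:
        raise ValueError("HIC needs at least 3 samples")
    if window_cap <= 0:
        raise ValueError("window_cap must be positive")
    dt = 1.0 / trace.fps
    max_w = max(1, int(math.floor(window_cap * trace.fps + 1e-9)))
    max_w = min(max_w, n - 1)
    # cumulative trapezoidal integral of a(t)
    I = np.concatenate([[0.0], np.cumsum(0.5 * (a[1:] + a[:-1]) * dt)])
    best_val, best_i, best_w = -1.0, 0, 1
    for w in range(1, max_w + 1):
        dur = w * dt
        vals = dur * (np.maximum(I[w:] - I[:-w], 0.0) / dur) ** 2.5
        i = int(np.argmax(vals))
        if vals[i] > best_val:
            best_val, best_i, best_w = float(vals[i]), i, w
    degenerate = best_val <= 0.0
    t1 = trace.t0 + best_i * dt
    return HICResult(max(best_val, 0.0), t1, t1 + best_w * dt,
                     window_cap=window_cap, degenerate=degenerate)


def compute_hic_exhaustive(trace: AccelerationTrace, window_cap: float = DEFAULT_WINDOW_CAP) -> HICResult:
    """Plain double-loop reference implementation of the windowed HIC.

    Kept as the independent oracle any optimized search must match exactly.
    """
    a = trace.samples
    n = a.size
    if n < 3:
        raise ValueError("HIC needs at least 3 samples")
    dt = 1.0 / trace.fps
    max_w = max(1, int(math.floor(window_cap * trace.fps + 1e-9)))
    max_w = min(max_w, n - 1)
    best_val, best_i, best_w = -1.0, 0, 1
    for i in range(n - 1):
        integral = 0.0
        for w in range(1, max_w + 1):
            j = i + w
            if j >= n:
                break
            integral += 0.5 * (a[j] + a[j - 1]) * dt
            dur = w * dt
            val = dur * (max(integral, 0.0) / dur) ** 2.5
            if val > best_val:
                best_val, best_i, best_w = val, i, w
    t1 = trace.t0 + best_i * dt
    return HICResult(max(best_val, 0.0), t1, t1 + best_w * dt,
                     window_cap=window_cap, degenerate=best_val <= 0.0)


def classify_severity(hic: float, thresholds: SeverityThresholds | None = None) -> SeverityLabel:
    """Map a HIC score onto the four-level severity scale.

    Half-open intervals, boundaries assigned upward:
    [0, 250) no injury, [250, 700) minor, [700, 1000) moderate,
    [1000, inf) heavy.
    """
    if hic < 0 or not math.isfinite(hic):
        raise ValueError("HIC must be finite and non-negative")
    th = thresholds or SeverityThresholds()
    if hic < th.t_minor:
        sev = SeverityClass.NO_INJURY
    elif hic < th.t_moderate:
        sev = SeverityClass.MINOR
    elif hic < th.t_heavy:
        sev = SeverityClass.MODERATE
    else:
        sev = SeverityClass.HEAVY
    return SeverityLabel(sev, float(hic))
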