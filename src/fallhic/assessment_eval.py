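"""Injury classification, the four-outcome metric suite, and the pipeline.

Severity prediction over a test set is summarized by a 4x4 confusion matrix
over the ordered classes {No, Minor, Moderate, Heavy}.  The evaluation
convention collapses it to binary-style outcome counts:

* TN — no-injury clips classified as no injury;
* FP — no-injury clips classified as any injury;
* TP — injured clips classified as their exact injury class;
* FN — injured clips classified as anything else (including no injury or a
  wrong injury class).

Under this convention TP + TN is exactly the matrix diagonal, so the
accuracy formula (TP + TN) / total coincides with multi-class accuracy.
Sensitivity, specificity, accuracy, precision and F-score are the usual
ratios of these counts.

Classifiers (random forest, linear- and RBF-kernel SVM) consume a small
per-clip feature vector derived solely from the assessed acceleration trace
and fall kinematics — peak acceleration, HIC, impact-window duration,
pre-impact fall duration, bounce-peak ratio, mean descent speed — so they
add robustness over direct HIC thresholding rather than new information.
A threshold-only mode (no learned classifier) applies the severity scale
directly.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .skeleton_io import KeypointSequence, detect_missing, DEFAULT_MISSING_THRESHOLD
from .keypoint_repair import (
    FLAG_EXTRAPOLATED, RepairModel, linear_interpolation_repair, repair_forward,
)
from .pose_lifting import LifterModel, Pose3DSequence, lift_sequence
from .head_injury import (
    DEFAULT_WINDOW_CAP, AccelerationTrace, HICResult, SeverityClass,
    SeverityThresholds, classify_severity, compute_hic, derive_acceleration,
    head_center,
)

CLASSES = (SeverityClass.NO_INJURY, SeverityClass.MINOR,
           SeverityClass.MODERATE, SeverityClass.HEAVY)
CLASS_NAMES = tuple(str(c) for c in CLASSES)


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage={stage}: {cause}")
        self.stage = stage
        self.cause = cause


# ---- confusion matrix and metrics ---------------------------------------


@dataclass
class ConfusionMatrix4:
    """counts[true][predicted] over {No, Minor, Moderate, Heavy}."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (4, 4):
            raise ValueError("confusion matrix must be 4x4")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_labels(cls, true: Sequence[int], pred: Sequence[int]) -> "ConfusionMatrix4":
        counts = np.zeros((4, 4), dtype=int)
        for t, p in zip(true, pred, strict=True):
            counts[int(t), int(p)] += 1
        return cls(counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_text(self) -> str:
        """Labeled tab-delimited export."""
        lines = ["true\\pred\t" + "\t".join(CLASS_NAMES)]
        for i, name in enumerate(CLASS_NAMES):
            lines.append(name + "\t" + "\t".join(str(c) for c in self.counts[i]))
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class OutcomeCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("outcome counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def outcome_counts(cm: ConfusionMatrix4) -> OutcomeCounts:
    """Collapse the 4-class matrix to TP/FP/TN/FN (convention in module doc)."""
    c = cm.counts
    tn = int(c[0, 0])
    fp = int(c[0, 1:].sum())
    tp = int(np.diag(c)[1:].sum())
    fn = int(c[1:].sum() - tp)
    return OutcomeCounts(TP=tp, FP=fp, TN=tn, FN=fn)


@dataclass(frozen=True)
class MetricsReport:
    """The five evaluation ratios; NaN fields are listed in ``undefined``."""

    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    f_score: float
    undefined: frozenset[str] = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "f_score": self.f_score,
        }


def _ratio(num: int, den: int, name: str, undefined: set[str]) -> float:
    if den == 0:
        undefined.add(name)
        return float("nan")
    return num / den


def compute_metrics(oc: OutcomeCounts) -> MetricsReport:
    """Sensitivity, specificity, accuracy, precision and F-score.

    A metric whose denominator is zero is reported as NaN and named in
    ``undefined`` rather than silently set to 0.
    """
    undefined: set[str] = set()
    return MetricsReport(
        sensitivity=_ratio(oc.TP, oc.TP + oc.FN, "sensitivity", undefined),
        specificity=_ratio(oc.TN, oc.TN + oc.FP, "specificity", undefined),
        accuracy=_ratio(oc.TP + oc.TN, oc.total, "accuracy", undefined),
        precision=_ratio(oc.TP, oc.TP + oc.FP, "precision", undefined),
        f_score=_ratio(2 * oc.TP, 2 * oc.TP + oc.FP + oc.FN, "f_score", undefined),
        undefined=frozenset(undefined),
    )


def percent(p: float) -> float:
    """Proportion -> percent, rounded half away from zero to 2 decimals."""
    if math.isnan(p):
        return float("nan")
    q = Decimal(repr(p * 100)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    return float(q)


# ---- per-clip features ---------------------------------------------------

FEATURE_NAMES = (
    "peak_accel_g", "hic", "impact_duration_s",
    "fall_duration_s", "bounce_ratio", "descent_speed_mps",
)


@dataclass(frozen=True)
class FeatureVector:
    """Per-clip features derived from the assessed acceleration trace."""

    peak_accel_g: float
    hic: float
    impact_duration_s: float
    fall_duration_s: float
    bounce_ratio: float
    descent_speed_mps: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES])


def extract_features(
    trace: AccelerationTrace,
    hic_result: HICResult | None = None,
    window_cap: float = DEFAULT_WINDOW_CAP,
) -> FeatureVector:
    """Summarize a resultant-acceleration trace into classifier features.

    The pre-impact fall duration is the contiguous near-1 g run (free
    flight) immediately preceding the main peak; mean descent speed follows
    from uniform acceleration (g * t / 2).  The bounce ratio compares the
    largest post-impact excursion with the main peak.
    """
    if hic_result is None:
        hic_result = compute_hic(trace, window_cap)
    a = trace.samples
    peak_idx = int(np.argmax(a))
    peak = float(a[peak_idx])

    # walk back out of the pulse, then count the free-flight run
    i = peak_idx
    while i > 0 and a[i - 1] > 1.3:
        i -= 1
    n_flight = 0
    while i > 0 and 0.7 < a[i - 1] < 1.3:
        n_flight += 1
        i -= 1
    fall_duration = n_flight / trace.fps

    # leave the main pulse forwards, then look for a secondary excursion
    j = peak_idx
    while j < a.size - 1 and a[j + 1] > 1.3:
        j += 1
    bounce_peak = float(a[j + 1:].max()) if j + 1 < a.size else 0.0
    bounce_ratio = bounce_peak / peak if peak > 0 else 0.0

    from .head_injury import G  # local import to avoid polluting module ns
    return FeatureVector(
        peak_accel_g=peak,
        hic=float(hic_result.hic),
        impact_duration_s=float(hic_result.t2 - hic_result.t1),
        fall_duration_s=float(fall_duration),
        bounce_ratio=float(min(bounce_ratio, 1.0)),
        descent_speed_mps=float(G * fall_duration / 2.0),
    )


# ---- classifiers ----------------------------------------------------------


def train_classifier(
    features: np.ndarray,
    labels: Sequence[int],
    kind: str = "rf",
    hyperparameters: dict | None = None,
    seed: int = 0,
):
    """Fit an injury-severity classifier on per-clip feature vectors.

    ``kind`` is one of ``rf`` (random forest: 500 trees, sqrt(p) features
    per split), ``svm_linear`` or ``svm_rbf`` (C = 1; RBF gamma = 1/p);
    SVM inputs are standardized.  Deterministic given the seed.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be (n, p) aligned with labels")
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    hp = hyperparameters or {}
    if kind == "rf":
        clf = RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 500),
            max_features=hp.get("max_features", "sqrt"),
            random_state=seed,
        )
    elif kind == "svm_linear":
        clf = Pipeline([
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="linear", C=hp.get("C", 1.0), random_state=seed)),
        ])
    elif kind == "svm_rbf":
        clf = Pipeline([
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="rbf", C=hp.get("C", 1.0),
                        gamma=hp.get("gamma", 1.0 / X.shape[1]), random_state=seed)),
        ])
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    clf.fit(X, y)
    return clf


def evaluate_classifier(
    clf, features: np.ndarray, labels: Sequence[int]
) -> tuple[ConfusionMatrix4, MetricsReport]:
    """Confusion matrix (rows ordered No/Minor/Moderate/Heavy) + metrics."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] == 0:
        raise ValueError("empty test set")
    pred = clf.predict(X)
    cm = ConfusionMatrix4.from_labels(y, pred)
    return cm, compute_metrics(outcome_counts(cm))


def hic_threshold_predict(
    features: np.ndarray, thresholds: SeverityThresholds | None = None
) -> np.ndarray:
    """No-ML mode: classify by applying the severity scale to the HIC feature."""
    X = np.asarray(features, dtype=float)
    hic_col = FEATURE_NAMES.index("hic")
    return np.array([int(classify_severity(h, thresholds).severity) for h in X[:, hic_col]])


# ---- end-to-end assessment -----------------------------------------------


@dataclass
class AssessConfig:
    missing_threshold: float = DEFAULT_MISSING_THRESHOLD
    smoothing_window: int | None = None  # default: ~58 ms span at the clip fps
    window_cap: float = DEFAULT_WINDOW_CAP
    thresholds: SeverityThresholds = field(default_factory=SeverityThresholds)
    subtract_gravity: bool = False
    head_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)


def assess(
    seq: KeypointSequence,
    repair_model: RepairModel | None = None,
    lifter_model: LifterModel | None = None,
    pose3d: Pose3DSequence | None = None,
    config: AssessConfig | None = None,
) -> dict:
    """Run the full per-clip pipeline and return a serializable report.

    Stages: missing-joint detection, recurrent repair (or the linear
    baseline when no repair model is supplied), 2D-to-3D lifting (skipped
    when a caller-supplied 3D sequence is given), head-center extraction,
    acceleration derivation, windowed HIC, severity classification.  Any
    stage failure is re-raised as :class:`StageError` naming the stage.
    The alert flag is true for any severity at or above minor injury.
    """
    cfg = config or AssessConfig()
    timings: dict[str, float] = {}

    def run(stage, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, exc) from exc
        timings[stage] = time.perf_counter() - t0
        return result

    gated = run("detect_missing", lambda: detect_missing(seq, cfg.missing_threshold))
    observed_mask = gated.mask.copy()

    if repair_model is not None:
        repaired = run("repair", lambda: repair_forward(repair_model, gated))
    else:
        repaired = run("repair", lambda: linear_interpolation_repair(gated))
    flags = repaired.flags
    n_joints_total = flags.size
    frac_imputed = float(np.sum(flags != "observed") / n_joints_total)
    any_extrapolated = bool(np.any(flags == FLAG_EXTRAPOLATED))

    if pose3d is None:
        if lifter_model is None:
            raise StageError("lift", ValueError(
                "no lifter model supplied and no 3D sequence given"))
        pose3d = run("lift", lambda: lift_sequence(lifter_model, repaired))

    centers, low_conf = run("head_center", lambda: head_center(
        pose3d, available=observed_mask, offset=cfg.head_offset))
    trace = run("derive_acceleration", lambda: derive_acceleration(
        centers, pose3d.fps, cfg.smoothing_window, cfg.subtract_gravity))
    hic_result = run("compute_hic", lambda: compute_hic(trace, cfg.window_cap))
    label = run("classify_severity",
                lambda: classify_severity(hic_result.hic, cfg.thresholds))

    return {
        "format": "fallhic.assessment",
        "version": 1,
        "hic": hic_result.hic,
        "hic_window": [hic_result.t1, hic_result.t2],
        "severity": int(label.severity),
        "severity_name": str(label.severity),
        "alert": label.severity >= SeverityClass.MINOR,
        "quality": {
            "fraction_imputed": frac_imputed,
            "extrapolated_joints": any_extrapolated,
            "low_confidence_head_frames": int(low_conf.sum()),
            "repair_mode": "model" if repair_model is not None else "linear",
        },
        "timings_s": timings,
    }
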