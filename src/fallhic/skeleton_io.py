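"""Data model and I/O for BODY_25 2D keypoint sequences.

The 25-joint skeleton layout ("BODY_25") is the per-frame output of common
2D pose estimators: each detected person carries a flat list of 75 numbers,
``[x0, y0, c0, ..., x24, y24, c24]``, where ``(x, y)`` are pixel coordinates
(origin top-left, y increasing downward) and ``c`` is a detection confidence
in [0, 1].  Joint 0 is the nose, joint 1 the neck, joint 8 the mid-hip and
joints 15-18 the eyes and ears.

A :class:`KeypointSequence` bundles the per-frame coordinate and confidence
arrays with a per-joint *missingness mask* (1 = observed, 0 = missing), the
capture frame rate, and a pixel-to-meter scale at the subject's depth.  The
mask implements the keep/forget gate of the repair stage: downstream code
treats mask-0 joints as absent regardless of their stored coordinates.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

N_JOINTS = 25

#: BODY_25 joint names in canonical order.
BODY_25_NAMES = (
    "Nose", "Neck", "RShoulder", "RElbow", "RWrist",
    "LShoulder", "LElbow", "LWrist", "MidHip", "RHip",
    "RKnee", "RAnkle", "LHip", "LKnee", "LAnkle",
    "REye", "LEye", "REar", "LEar", "LBigToe",
    "LSmallToe", "LHeel", "RBigToe", "RSmallToe", "RHeel",
)

NOSE, NECK, MIDHIP = 0, 1, 8
#: Joints belonging to the head region (nose, eyes, ears).
HEAD_JOINTS = (0, 15, 16, 17, 18)

#: Default confidence at or below which a joint is declared missing.  Pose
#: estimators emit an exact 0 for undetected joints; the small positive
#: margin also catches near-zero noise.
DEFAULT_MISSING_THRESHOLD = 0.05


class FormatError(ValueError):
    """Raised when a keypoint JSON document does not follow the dialect."""


@dataclass(frozen=True)
class KeypointFrame:
    """One frame of a 2D skeleton: 25 joints as (x_px, y_px, confidence)."""

    frame_index: int
    joints: np.ndarray  # (25, 3) float64

    def __post_init__(self) -> None:
        joints = np.asarray(self.joints, dtype=float)
        if joints.shape != (N_JOINTS, 3):
            raise FormatError(
                f"frame {self.frame_index}: expected {N_JOINTS} joints x 3, "
                f"got array of shape {joints.shape}"
            )
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        conf = joints[:, 2]
        if np.any((conf < 0) | (conf > 1) | ~np.isfinite(conf)):
            raise FormatError(
                f"frame {self.frame_index}: confidences must lie in [0, 1]"
            )
        object.__setattr__(self, "joints", joints)


@dataclass
class KeypointSequence:
    """A time-ordered 2D skeleton sequence with a per-joint missingness mask.

    Parameters
    ----------
    coords:
        ``(T, 25, 2)`` pixel coordinates.
    conf:
        ``(T, 25)`` detection confidences in [0, 1].
    mask:
        ``(T, 25)`` binary gate; 1 = observed/kept, 0 = missing/forgotten.
    fps:
        Capture rate, frames per second (> 0).
    scale:
        Meters per pixel at the subject's depth (> 0).
    frame_indices:
        Strictly increasing original frame numbers; defaults to 0..T-1.
    flags:
        Optional ``(T, 25)`` array of per-joint quality strings
        ("observed" / "imputed" / "extrapolated") set by the repair stage.
    """

    coords: np.ndarray
    conf: np.ndarray
    mask: np.ndarray
    fps: float
    scale: float
    frame_indices: np.ndarray | None = None
    flags: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.conf = np.asarray(self.conf, dtype=float)
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (N_JOINTS, 2):
            raise ValueError(f"coords must be (T, {N_JOINTS}, 2), got {self.coords.shape}")
        T = self.coords.shape[0]
        if self.conf.shape != (T, N_JOINTS) or self.mask.shape != (T, N_JOINTS):
            raise ValueError("conf and mask must have shape (T, 25) matching coords")
        if not (self.fps > 0 and math.isfinite(self.fps)):
            raise ValueError("fps must be strictly positive")
        if not (self.scale > 0 and math.isfinite(self.scale)):
            raise ValueError("scale must be strictly positive")
        if np.any((self.conf < 0) | (self.conf > 1)):
            raise ValueError("confidences must lie in [0, 1]")
        if self.frame_indices is None:
            self.frame_indices = np.arange(T)
        else:
            self.frame_indices = np.asarray(self.frame_indices, dtype=int)
            if self.frame_indices.shape != (T,):
                raise ValueError("frame_indices must have length T")
            if T > 1 and np.any(np.diff(self.frame_indices) <= 0):
                raise ValueError("frame_indices must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, t: int) -> KeypointFrame:
        joints = np.concatenate([self.coords[t], self.conf[t, :, None]], axis=1)
        return KeypointFrame(int(self.frame_indices[t]), joints)

    @property
    def frames(self) -> list[KeypointFrame]:
        return [self.frame(t) for t in range(self.n_frames)]

    def copy(self) -> "KeypointSequence":
        return KeypointSequence(
            self.coords.copy(), self.conf.copy(), self.mask.copy(),
            self.fps, self.scale, self.frame_indices.copy(),
            None if self.flags is None else self.flags.copy(),
        )

    # ---- internal serialized format -------------------------------------

    def to_json(self) -> dict:
        """Single-document serialization (frames, mask, fps, scale)."""
        doc = {
            "format": "fallhic.keypoint_sequence",
            "version": 1,
            "fps": self.fps,
            "scale": self.scale,
            "frame_indices": self.frame_indices.tolist(),
            "coords": self.coords.tolist(),
            "conf": self.conf.tolist(),
            "mask": self.mask.tolist(),
        }
        if self.flags is not None:
            doc["flags"] = self.flags.tolist()
        return doc

    @classmethod
    def from_json(cls, doc: dict) -> "KeypointSequence":
        if doc.get("format") != "fallhic.keypoint_sequence":
            raise FormatError("not a serialized keypoint sequence")
        flags = doc.get("flags")
        return cls(
            np.asarray(doc["coords"]), np.asarray(doc["conf"]),
            np.asarray(doc["mask"]), doc["fps"], doc["scale"],
            np.asarray(doc["frame_indices"]),
            None if flags is None else np.asarray(flags, dtype=object),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json()))

    @classmethod
    def load(cls, path: str | Path) -> "KeypointSequence":
        return cls.from_json(json.loads(Path(path).read_text()))


def _select_person(people: list[dict], frame_name: str) -> np.ndarray:
    """Pick one person per frame: greatest total confidence wins."""
    best = None
    best_score = -np.inf
    for person in people:
        pose = person.get("pose_keypoints_2d")
        if pose is None or len(pose) != 3 * N_JOINTS:
            n = "missing" if pose is None else len(pose)
            raise FormatError(
                f"{frame_name}: pose_keypoints_2d must hold {3 * N_JOINTS} "
                f"numbers, got {n}"
            )
        arr = np.asarray(pose, dtype=float).reshape(N_JOINTS, 3)
        score = float(np.nansum(arr[:, 2]))
        if score > best_score:
            best_score = score
            best = arr
    return best


_FRAME_NUM_RE = re.compile(r"(\d+)")


def _frame_sort_key(path: Path) -> str:
    return path.name


def read_openpose_sequence(
    source: str | Path | Iterable,
    fps: float,
    scale: float,
    missing_threshold: float = DEFAULT_MISSING_THRESHOLD,
) -> KeypointSequence:
    """Read a per-frame keypoint JSON dialect into a :class:`KeypointSequence`.

    ``source`` may be a directory of ``*_keypoints.json`` files (consumed in
    lexicographic order), an ordered iterable of file paths, or an ordered
    iterable of already-parsed frame documents.  Each document must look like
    ``{"version": ..., "people": [{"pose_keypoints_2d": [...75 numbers...]}]}``.
    An empty ``people`` array yields an all-missing frame.  When several
    people are present, the one with the greatest summed confidence is kept.

    ``fps`` (frames/s) and ``scale`` (meters/pixel) are required: neither is
    recoverable from the keypoint files themselves.
    """
    docs: list[tuple[str, dict]] = []
    if isinstance(source, (str, Path)):
        directory = Path(source)
        paths = sorted(directory.glob("*_keypoints.json"), key=_frame_sort_key)
        if not paths:
            paths = sorted(directory.glob("*.json"), key=_frame_sort_key)
        for p in paths:
            try:
                docs.append((p.name, json.loads(p.read_text())))
            except json.JSONDecodeError as exc:
                raise FormatError(f"{p.name}: malformed JSON ({exc})") from exc
    else:
        for i, item in enumerate(source):
            if isinstance(item, (str, Path)):
                p = Path(item)
                try:
                    docs.append((p.name, json.loads(p.read_text())))
                except json.JSONDecodeError as exc:
                    raise FormatError(f"{p.name}: malformed JSON ({exc})") from exc
            elif isinstance(item, dict):
                docs.append((f"frame {i}", item))
            else:
                raise FormatError(f"frame {i}: unsupported source element {type(item)!r}")

    T = len(docs)
    coords = np.zeros((T, N_JOINTS, 2))
    conf = np.zeros((T, N_JOINTS))
    indices = np.zeros(T, dtype=int)
    for t, (name, doc) in enumerate(docs):
        if not isinstance(doc, dict) or "people" not in doc:
            raise FormatError(f"{name}: document has no 'people' array")
        m = _FRAME_NUM_RE.findall(name)
        indices[t] = int(m[-1]) if m and not name.startswith("frame ") else t
        people = doc["people"]
        if people:
            arr = _select_person(people, name)
            coords[t] = arr[:, :2]
            conf[t] = np.clip(np.nan_to_num(arr[:, 2]), 0.0, 1.0)
    if T > 1 and np.any(np.diff(indices) <= 0):
        indices = np.arange(T)

    mask = np.ones((T, N_JOINTS), dtype=np.uint8)
    seq = KeypointSequence(coords, conf, mask, fps, scale, indices)
    return detect_missing(seq, missing_threshold)


def detect_missing(seq: KeypointSequence, threshold: float = DEFAULT_MISSING_THRESHOLD) -> KeypointSequence:
    """Recompute the missingness mask from confidences and coordinate finiteness.

    A joint is missing iff its confidence is <= ``threshold`` or either
    coordinate is non-finite.  The operation is idempotent and monotone in
    the threshold (raising it never resurrects a missing joint).
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    out = seq.copy()
    finite = np.isfinite(seq.coords).all(axis=2)
    out.mask = ((seq.conf > threshold) & finite).astype(np.uint8)
    return out


def write_openpose_sequence(seq: KeypointSequence, destination: str | Path) -> list[Path]:
    """Write one JSON document per frame in the consumed dialect.

    Frames whose joints are all at (0, 0) with zero confidence (the encoding
    an estimator uses for a frame with no detection) are written with an
    empty ``people`` array.  Reading the written directory back reproduces
    coordinates, confidences and frame order bit-exactly.
    """
    directory = Path(destination)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create destination {directory}: {exc}") from exc
    written = []
    for t in range(seq.n_frames):
        idx = int(seq.frame_indices[t])
        if not np.any(seq.conf[t]) and not np.any(seq.coords[t]):
            people = []
        else:
            flat = np.concatenate(
                [seq.coords[t], seq.conf[t, :, None]], axis=1
            ).reshape(-1)
            people = [{"person_id": [-1], "pose_keypoints_2d": flat.tolist()}]
        doc = {"version": 1.3, "people": people}
        path = directory / f"{idx:012d}_keypoints.json"
        try:
            path.write_text(json.dumps(doc))
        except OSError as exc:
            raise IOError(f"cannot write {path}: {exc}") from exc
        written.append(path)
    return written
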