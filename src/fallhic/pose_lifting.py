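"""Per-frame 2D-to-3D pose lifting with a residual multilayer network.

A single camera view gives 25 joint positions in pixels; the lifter regresses
the corresponding root-relative 3D joint positions in meters.  The network is
the simple-but-effective residual architecture used for this task: a linear
embedding to a wide hidden space (1024 units), followed by residual blocks of
[linear -> batch standardization -> ReLU -> dropout], and a linear output
head producing ``3n`` coordinates from a ``2n`` input.  Every linear layer's
per-unit incoming weight vector is constrained to norm <= 1 after each
optimizer step (max-norm regularization, applied jointly with batch
normalization).

Absolute placement is not recoverable from one view: the network predicts
neck-relative 3D offsets, and :func:`lift_sequence` anchors them in the lab
frame using the sequence's meters-per-pixel scale at the subject's depth
(pixel x -> lab x, pixel y -> negative lab z, depth fixed at the nominal
subject plane).  Vertical motion is therefore tracked up to a constant
offset, which is all the downstream acceleration stage needs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .skeleton_io import N_JOINTS, NECK, KeypointSequence

_EPS = 1e-5


class PreconditionError(ValueError):
    """Input violates a stage precondition (e.g. unrepaired sequence)."""


class TrainingError(RuntimeError):
    """Training diverged (non-finite loss)."""


@dataclass
class Pose3DSequence:
    """Time-ordered 3D joint positions: ``(T, 25, 3)`` meters, lab frame.

    Lab frame convention: x lateral, y depth (away from the camera),
    z vertical upward.
    """

    joints: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.joints = np.asarray(self.joints, dtype=float)
        if self.joints.ndim != 3 or self.joints.shape[1:] != (N_JOINTS, 3):
            raise ValueError(f"joints must be (T, {N_JOINTS}, 3), got {self.joints.shape}")
        if not np.all(np.isfinite(self.joints)):
            raise ValueError("joint coordinates must be finite")
        if not (self.fps > 0 and math.isfinite(self.fps)):
            raise ValueError("fps must be strictly positive")

    @property
    def n_frames(self) -> int:
        return self.joints.shape[0]


@dataclass
class LifterConfig:
    """Architecture and optimization settings for the lifting network."""

    width: int = 1024
    n_blocks: int = 2            # residual blocks
    block_depth: int = 2         # linear layers per block
    dropout: float = 0.5
    learning_rate: float = 1e-3  # with exponential decay
    decay_rate: float = 0.96
    decay_steps: int = 1000
    batch_size: int = 32
    epochs: int = 25
    max_norm: float = 1.0
    seed: int = 0

    input_dim: int = 2 * N_JOINTS
    output_dim: int = 3 * N_JOINTS


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class _BatchNorm:
    """Per-feature batch standardization with running inference statistics."""

    def __init__(self, dim: int, momentum: float = 0.1):
        self.gamma = np.ones(dim, dtype=np.float32)
        self.beta = np.zeros(dim, dtype=np.float32)
        self.running_mean = np.zeros(dim, dtype=np.float32)
        self.running_var = np.ones(dim, dtype=np.float32)
        self.momentum = momentum

    def forward(self, x: np.ndarray, train: bool):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + _EPS)
        xhat = (x - mu) * inv
        y = self.gamma * xhat + self.beta
        cache = (xhat, inv)
        return y, cache

    def backward(self, dy: np.ndarray, cache, train: bool):
        xhat, inv = cache
        dgamma = (dy * xhat).sum(axis=0)
        dbeta = dy.sum(axis=0)
        if train:
            n = dy.shape[0]
            dx = (self.gamma * inv) * (
                dy - dy.mean(axis=0) - xhat * (dy * xhat).sum(axis=0) / n
            )
        else:
            dx = dy * self.gamma * inv
        return dx, dgamma, dbeta


class LifterModel:
    """Residual MLP mapping 50 2D coordinates to 75 root-relative 3D ones."""

    def __init__(self, config: LifterConfig | None = None, rng: np.random.Generator | None = None):
        self.config = config or LifterConfig()
        cfg = self.config
        rng = rng or np.random.default_rng(cfg.seed)

        def init(n_in, n_out):
            s = math.sqrt(2.0 / n_in)
            return (rng.standard_normal((n_in, n_out)) * s).astype(np.float32)

        self.W_in = init(cfg.input_dim, cfg.width)
        self.b_in = np.zeros(cfg.width, dtype=np.float32)
        self.bn_in = _BatchNorm(cfg.width)
        self.blocks: list[list[tuple]] = []
        for _ in range(cfg.n_blocks):
            layers = []
            for _ in range(cfg.block_depth):
                layers.append([init(cfg.width, cfg.width),
                               np.zeros(cfg.width, dtype=np.float32),
                               _BatchNorm(cfg.width)])
            self.blocks.append(layers)
        self.W_out = init(cfg.width, cfg.output_dim)
        self.b_out = np.zeros(cfg.output_dim, dtype=np.float32)
        self._project_max_norm()

    # ---- forward / backward --------------------------------------------

    def _dropout_mask(self, shape, rng: np.random.Generator | None):
        p = self.config.dropout
        if rng is None or p <= 0:
            return None
        return (rng.random(shape) >= p).astype(np.float32) / (1.0 - p)

    def forward(self, X: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """Run the network; returns (output, cache). Dropout only if ``train``."""
        X = np.asarray(X, dtype=np.float32)
        cache: dict = {"X": X, "train": train}
        h = X @ self.W_in + self.b_in
        cache["pre_in"] = h
        h, cache["bn_in"] = self.bn_in.forward(h, train)
        cache["relu_in"] = h > 0
        h = _relu(h)
        dm = self._dropout_mask(h.shape, rng if train else None)
        cache["drop_in"] = dm
        if dm is not None:
            h = h * dm
        cache["block_caches"] = []
        for layers in self.blocks:
            r = h
            lcaches = []
            for W, b, bn in layers:
                inp = h
                z = h @ W + b
                zbn, bncache = bn.forward(z, train)
                rl = zbn > 0
                h = _relu(zbn)
                dm = self._dropout_mask(h.shape, rng if train else None)
                if dm is not None:
                    h = h * dm
                lcaches.append((inp, bncache, rl, dm))
            cache["block_caches"].append((r, lcaches, h))
            h = h + r
        cache["h_final"] = h
        out = h @ self.W_out + self.b_out
        return out, cache

    def predict(self, X: np.ndarray) -> np.ndarray:
        out, _ = self.forward(X, train=False)
        return out

    def backward(self, dout: np.ndarray, cache) -> dict:
        """Gradients of a scalar loss given d(loss)/d(output)."""
        train = cache["train"]
        grads: dict = {}
        h_final = cache["h_final"]
        grads["W_out"] = h_final.T @ dout
        grads["b_out"] = dout.sum(axis=0)
        dh = dout @ self.W_out.T
        grads["blocks"] = []
        for bi in range(len(self.blocks) - 1, -1, -1):
            layers = self.blocks[bi]
            r, lcaches, _ = cache["block_caches"][bi]
            dres = dh  # gradient through the skip connection
            dcur = dh
            lgrads = []
            for li in range(len(layers) - 1, -1, -1):
                W, b, bn = layers[li]
                inp, bncache, rl, dm = lcaches[li]
                if dm is not None:
                    dcur = dcur * dm
                dcur = dcur * rl
                dcur, dgamma, dbeta = bn.backward(dcur, bncache, train)
                lgrads.append({"W": inp.T @ dcur, "b": dcur.sum(axis=0),
                               "gamma": dgamma, "beta": dbeta})
                dcur = dcur @ W.T
            lgrads.reverse()
            grads["blocks"].append(lgrads)
            dh = dcur + dres
        grads["blocks"].reverse()
        dm = cache["drop_in"]
        if dm is not None:
            dh = dh * dm
        dh = dh * cache["relu_in"]
        dh, grads["gamma_in"], grads["beta_in"] = self.bn_in.backward(dh, cache["bn_in"], train)
        grads["W_in"] = cache["X"].T @ dh
        grads["b_in"] = dh.sum(axis=0)
        return grads

    # ---- parameter plumbing --------------------------------------------

    def _params(self):
        """(name, array) pairs for all trainable parameters."""
        yield "W_in", self.W_in
        yield "b_in", self.b_in
        yield "gamma_in", self.bn_in.gamma
        yield "beta_in", self.bn_in.beta
        for bi, layers in enumerate(self.blocks):
            for li, (W, b, bn) in enumerate(layers):
                yield f"blocks.{bi}.{li}.W", W
                yield f"blocks.{bi}.{li}.b", b
                yield f"blocks.{bi}.{li}.gamma", bn.gamma
                yield f"blocks.{bi}.{li}.beta", bn.beta
        yield "W_out", self.W_out
        yield "b_out", self.b_out

    def _grad_by_name(self, grads: dict, name: str) -> np.ndarray:
        if name.startswith("blocks."):
            _, bi, li, leaf = name.split(".")
            return grads["blocks"][int(bi)][int(li)][leaf]
        return grads[name]

    def _set_param(self, name: str, value: np.ndarray) -> None:
        if name.startswith("blocks."):
            _, bi, li, leaf = name.split(".")
            layer = self.blocks[int(bi)][int(li)]
            if leaf == "W":
                layer[0][...] = value
            elif leaf == "b":
                layer[1][...] = value
            elif leaf == "gamma":
                layer[2].gamma[...] = value
            else:
                layer[2].beta[...] = value
        elif name in ("gamma_in", "beta_in"):
            setattr(self.bn_in, {"gamma_in": "gamma", "beta_in": "beta"}[name], value)
        else:
            getattr(self, name)[...] = value

    def weight_matrices(self) -> list[np.ndarray]:
        mats = [self.W_in, self.W_out]
        for layers in self.blocks:
            for W, _, _ in layers:
                mats.append(W)
        return mats

    def _project_max_norm(self) -> None:
        """Clip each unit's incoming weight vector to norm <= max_norm."""
        c = self.config.max_norm
        for W in self.weight_matrices():
            norms = np.sqrt((W ** 2).sum(axis=0, keepdims=True))
            np.divide(W, np.maximum(norms / c, 1.0), out=W)

    def max_unit_norm(self) -> float:
        return max(float(np.sqrt((W ** 2).sum(axis=0)).max()) for W in self.weight_matrices())

    # ---- checkpointing --------------------------------------------------

    def save(self, path: str | Path) -> None:
        doc = {
            "format": "fallhic.lifter_checkpoint",
            "version": 1,
            "config": asdict(self.config),
            "params": {n: p.tolist() for n, p in self._params()},
            "running": {
                "bn_in": [self.bn_in.running_mean.tolist(), self.bn_in.running_var.tolist()],
                "blocks": [
                    [[bn.running_mean.tolist(), bn.running_var.tolist()]
                     for _, _, bn in layers]
                    for layers in self.blocks
                ],
            },
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path: str | Path) -> "LifterModel":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != "fallhic.lifter_checkpoint":
            raise ValueError("not a lifter checkpoint")
        model = cls(LifterConfig(**doc["config"]))
        for n, v in doc["params"].items():
            model._set_param(n, np.asarray(v, dtype=np.float32))
        rm, rv = doc["running"]["bn_in"]
        model.bn_in.running_mean = np.asarray(rm, dtype=np.float32)
        model.bn_in.running_var = np.asarray(rv, dtype=np.float32)
        for layers, saved in zip(model.blocks, doc["running"]["blocks"]):
            for (_, _, bn), (m, v) in zip(layers, saved):
                bn.running_mean = np.asarray(m, dtype=np.float32)
                bn.running_var = np.asarray(v, dtype=np.float32)
        return model


# ---- dataset construction and normalization -----------------------------


def normalize_frames_2d(seq: KeypointSequence) -> np.ndarray:
    """Neck-relative 2D input in meters at the subject depth: ``(T, 50)``."""
    rel = (seq.coords - seq.coords[:, NECK:NECK + 1, :]) * seq.scale
    return rel.reshape(seq.n_frames, -1)


def normalize_frames_3d(pose: Pose3DSequence) -> np.ndarray:
    """Neck-relative 3D target in meters: ``(T, 75)``."""
    rel = pose.joints - pose.joints[:, NECK:NECK + 1, :]
    return rel.reshape(pose.n_frames, -1)


def make_lifting_dataset(
    pairs: Sequence[tuple[KeypointSequence, Pose3DSequence]],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack (2D frame, 3D frame) training pairs from aligned sequences."""
    Xs, Ys = [], []
    for seq, pose in pairs:
        if seq.n_frames != pose.n_frames:
            raise ValueError("2D and 3D sequences must be frame-aligned")
        Xs.append(normalize_frames_2d(seq))
        Ys.append(normalize_frames_3d(pose))
    if not Xs:
        raise ValueError("empty dataset")
    return np.concatenate(Xs).astype(np.float32), np.concatenate(Ys).astype(np.float32)


def mean_per_joint_error(pred: np.ndarray, true: np.ndarray) -> float:
    """Mean Euclidean per-joint position error (meters) over frames."""
    d = (np.asarray(pred) - np.asarray(true)).reshape(-1, N_JOINTS, 3)
    return float(np.linalg.norm(d, axis=2).mean())


# ---- training ------------------------------------------------------------


def train_lifter(
    config: LifterConfig,
    X: np.ndarray,
    Y: np.ndarray,
    seed: int | None = None,
) -> tuple[LifterModel, list[float]]:
    """Fit the lifter by Adam on mean squared 3D error.

    The learning rate starts at ``config.learning_rate`` and decays by
    ``decay_rate`` every ``decay_steps`` optimizer steps; the per-unit
    max-norm constraint is re-projected after every update.  Deterministic
    given the seed.  Returns the model and the per-epoch training loss.
    """
    X = np.asarray(X, dtype=np.float32)
    Y = np.asarray(Y, dtype=np.float32)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0] or X.shape[0] == 0:
        raise ValueError("X and Y must be nonempty aligned 2D arrays")
    if X.shape[1] != config.input_dim or Y.shape[1] != config.output_dim:
        raise ValueError("dataset dimensions do not match the configured model")

    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    model = LifterModel(config, rng=np.random.default_rng(rng.integers(2 ** 31)))
    drop_rng = np.random.default_rng(rng.integers(2 ** 31))

    m_state = {n: np.zeros_like(p) for n, p in model._params()}
    v_state = {n: np.zeros_like(p) for n, p in model._params()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    N = X.shape[0]
    history: list[float] = []
    for _epoch in range(config.epochs):
        order = rng.permutation(N)
        losses = []
        for start in range(0, N, config.batch_size):
            idx = order[start:start + config.batch_size]
            if len(idx) < 2:
                continue  # batch standardization needs >= 2 samples
            xb, yb = X[idx], Y[idx]
            out, cache = model.forward(xb, train=True, rng=drop_rng)
            diff = out - yb
            loss = float(np.mean(diff ** 2))
            if not math.isfinite(loss):
                raise TrainingError("lifter training diverged (non-finite loss)")
            losses.append(loss)
            dout = (2.0 / diff.size) * diff
            grads = model.backward(dout, cache)
            step += 1
            lr = config.learning_rate * config.decay_rate ** (step / config.decay_steps)
            for name, p in model._params():
                g = model._grad_by_name(grads, name).astype(np.float32)
                m_state[name] = beta1 * m_state[name] + (1 - beta1) * g
                v_state[name] = beta2 * v_state[name] + (1 - beta2) * g * g
                mhat = m_state[name] / (1 - beta1 ** step)
                vhat = v_state[name] / (1 - beta2 ** step)
                p -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(np.float32)
            model._project_max_norm()
        history.append(float(np.mean(losses)) if losses else 0.0)
    return model, history


# ---- inference -----------------------------------------------------------


def lift_sequence(model: LifterModel, seq: KeypointSequence) -> Pose3DSequence:
    """Lift a fully repaired 2D sequence to 3D, frame by frame.

    Requires ``seq.mask`` to be all ones; a masked joint means the repair
    stage has not been run.  The network's neck-relative prediction is
    anchored in the lab frame from the neck's pixel position via the
    sequence scale (absolute depth is fixed at the nominal subject plane).
    """
    if not np.all(seq.mask == 1):
        raise PreconditionError(
            "sequence contains missing joints; run keypoint_repair first"
        )
    X = normalize_frames_2d(seq).astype(np.float32)
    rel = model.predict(X).astype(float).reshape(seq.n_frames, N_JOINTS, 3)
    neck_px = seq.coords[:, NECK, :]
    anchor = np.stack(
        [neck_px[:, 0] * seq.scale,
         np.zeros(seq.n_frames),
         -neck_px[:, 1] * seq.scale],
        axis=1,
    )
    joints = rel + anchor[:, None, :]
    return Pose3DSequence(joints, seq.fps)
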