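"""Recurrent gated repair of occluded 2D keypoint sequences.

Home-surveillance pose tracks lose joints to furniture, lighting and
self-occlusion.  Plain interpolation fails exactly when it matters: around
the impact, where trajectories have high curvature.  This module imputes
missing joints with a gated recurrent sequence model (the standard LSTM
recurrence: forget/input/output gates on a persistent cell state) that reads
each frame's *gated* coordinates — missing entries enter as zeros with a
parallel mask channel, so the recurrence "forgets" them and carries context
across the gap — and a linear output head that combines the per-frame hidden
states of a forward and a backward pass into coordinate predictions.

Two hard contracts:

* observed joints pass through bit-identically (the keep/forget gate is a
  contract, not a learned tendency);
* a frame's prediction depends only on frames within ``memory_horizon``
  (default 100) of it: sequences are processed in overlapping windows of
  that length and each frame takes its prediction from the window it is
  most central in.

The output head predicts a *residual* on top of the per-joint linear
interpolant of the observed samples, so an untrained model already realizes
interpolation and training only has to learn the systematic curvature that
interpolation misses.  Coordinates are window-normalized (neck-centered,
torso-scaled) before the recurrence; pixel-scale inputs would saturate the
sigmoid gates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .skeleton_io import MIDHIP, N_JOINTS, NECK, KeypointSequence
from .pose_lifting import TrainingError


class RepairError(ValueError):
    """The sequence cannot be repaired (e.g. a joint is never observed)."""


FLAG_OBSERVED = "observed"
FLAG_IMPUTED = "imputed"
FLAG_EXTRAPOLATED = "extrapolated"


@dataclass
class RepairConfig:
    hidden_size: int = 128
    memory_horizon: int = 100     # frames; hard context limit
    bidirectional: bool = True
    epochs: int = 300
    batch_size: int = 16
    train_window: int = 64        # frames per training crop (<= horizon)
    crops_per_seq: int = 4        # random crops per sequence per epoch
    optimizer: str = "adam"       # "adam" | "sgd" (momentum)
    learning_rate: float = 2e-3   # adam default; use ~0.02 for sgd
    lr_decay: float = 0.97        # per-epoch exponential decay
    momentum: float = 0.937       # sgd only
    weight_decay: float = 5e-4
    grad_clip: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.memory_horizon > 100:
            raise ValueError("memory_horizon must be <= 100 frames")
        if self.train_window > self.memory_horizon:
            raise ValueError("train_window must not exceed memory_horizon")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


_INPUT_DIM = 5 * N_JOINTS   # 50 gated coords + 25 mask bits + 50 interpolant
_OUTPUT_DIM = 2 * N_JOINTS


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -40, 40)))


def _lstm_forward(X: np.ndarray, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray):
    """Batched LSTM over (B, T, D); returns hidden states (B, T, H) + cache."""
    B, T, _ = X.shape
    H = Wh.shape[0]
    Hs = np.zeros((B, T, H))
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    caches = []
    for t in range(T):
        z = X[:, t] @ Wx + h @ Wh + b
        f = _sigmoid(z[:, :H])
        i = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c_new = f * c + i * g          # gated cell update
        tc = np.tanh(c_new)
        caches.append((X[:, t], h, c, f, i, g, o, tc))
        c = c_new
        h = o * tc
        Hs[:, t] = h
    return Hs, caches


def _lstm_backward(dHs: np.ndarray, caches, Wx: np.ndarray, Wh: np.ndarray):
    B, T, H = dHs.shape
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        x, h_prev, c_prev, f, i, g, o, tc = caches[t]
        dh = dHs[:, t] + dh_next
        do = dh * tc
        dc = dc_next + dh * o * (1.0 - tc ** 2)
        df = dc * c_prev
        di = dc * g
        dg = dc * i
        dc_next = dc * f
        dz = np.concatenate(
            [df * f * (1 - f), di * i * (1 - i), dg * (1 - g ** 2), do * o * (1 - o)],
            axis=1,
        )
        dWx += x.T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dh_next = dz @ Wh.T
    return dWx, dWh, db


class RepairModel:
    """Bidirectional gated recurrence + linear head over interp baseline."""

    def __init__(self, config: RepairConfig | None = None,
                 rng: np.random.Generator | None = None):
        self.config = config or RepairConfig()
        cfg = self.config
        rng = rng or np.random.default_rng(cfg.seed)
        H = cfg.hidden_size
        s = 1.0 / math.sqrt(H)
        self.params: dict[str, np.ndarray] = {}
        directions = ("f", "b") if cfg.bidirectional else ("f",)
        for d in directions:
            self.params[f"Wx_{d}"] = rng.uniform(-s, s, (_INPUT_DIM, 4 * H))
            self.params[f"Wh_{d}"] = rng.uniform(-s, s, (H, 4 * H))
            b = np.zeros(4 * H)
            b[:H] = 1.0  # forget-gate bias: start by retaining the cell
            self.params[f"b_{d}"] = b
        head_in = H * len(directions)
        # zero head: the untrained model reproduces the interpolant exactly
        self.params["W_out"] = np.zeros((head_in, _OUTPUT_DIM))
        self.params["b_out"] = np.zeros(_OUTPUT_DIM)

    @property
    def directions(self) -> tuple[str, ...]:
        return ("f", "b") if self.config.bidirectional else ("f",)

    def hidden_states(self, X: np.ndarray):
        """Forward (and reversed backward) hidden states, concatenated."""
        caches = {}
        hs = []
        Hs_f, caches["f"] = _lstm_forward(X, self.params["Wx_f"],
                                          self.params["Wh_f"], self.params["b_f"])
        hs.append(Hs_f)
        if self.config.bidirectional:
            Xr = X[:, ::-1]
            Hs_b, caches["b"] = _lstm_forward(Xr, self.params["Wx_b"],
                                              self.params["Wh_b"], self.params["b_b"])
            hs.append(Hs_b[:, ::-1])
        return np.concatenate(hs, axis=2), caches

    def predict_windows(self, X: np.ndarray, baseline: np.ndarray) -> np.ndarray:
        """Predicted normalized coordinates for a batch of windows."""
        Hcat, _ = self.hidden_states(X)
        return Hcat @ self.params["W_out"] + self.params["b_out"] + baseline

    # ---- checkpointing --------------------------------------------------

    def save(self, path: str | Path) -> None:
        doc = {
            "format": "fallhic.repair_checkpoint",
            "version": 1,
            "config": asdict(self.config),
            "params": {k: v.tolist() for k, v in self.params.items()},
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path: str | Path) -> "RepairModel":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != "fallhic.repair_checkpoint":
            raise ValueError("not a repair checkpoint")
        model = cls(RepairConfig(**doc["config"]))
        for k, v in doc["params"].items():
            model.params[k] = np.asarray(v, dtype=float)
        return model


# ---- window preparation --------------------------------------------------


def _window_stats(coords: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, float]:
    """Neck-centered, torso-scaled normalization from observed joints only."""
    obs = mask.astype(bool)
    neck_obs = obs[:, NECK]
    if neck_obs.any():
        center = coords[neck_obs, NECK].mean(axis=0)
    elif obs.any():
        center = coords[obs].mean(axis=0)
    else:
        center = np.zeros(2)
    both = obs[:, NECK] & obs[:, MIDHIP]
    if both.any():
        scale = float(np.linalg.norm(coords[both, NECK] - coords[both, MIDHIP], axis=1).mean())
    elif obs.any():
        scale = float(coords[obs].std())
    else:
        scale = 1.0
    return center, max(scale, 1e-6)


def _interp_baseline(norm_coords: np.ndarray, mask: np.ndarray):
    """Per-joint, per-axis linear interpolant of the observed samples.

    Joints unobserved in the whole window fall back to the window's mean
    observed position (locality over accuracy; the head must fix the rest).
    Returns (baseline (T,25,2), extrapolated (T,25) bool).
    """
    T = norm_coords.shape[0]
    base = norm_coords.copy()
    extrapolated = np.zeros((T, N_JOINTS), dtype=bool)
    obs = mask.astype(bool)
    fallback = norm_coords[obs].mean(axis=0) if obs.any() else np.zeros(2)
    for j in range(N_JOINTS):
        obs_t = np.flatnonzero(obs[:, j])
        miss_t = np.flatnonzero(~obs[:, j])
        if miss_t.size == 0:
            continue
        if obs_t.size == 0:
            base[miss_t, j] = fallback
            extrapolated[miss_t, j] = True
            continue
        for axis in (0, 1):
            base[miss_t, j, axis] = np.interp(miss_t, obs_t, norm_coords[obs_t, j, axis])
        extrapolated[:, j] = (~obs[:, j]) & (
            (np.arange(T) < obs_t[0]) | (np.arange(T) > obs_t[-1])
        )
    return base, extrapolated


def _prepare_window(coords: np.ndarray, mask: np.ndarray):
    """Normalize one window and build model input / baseline.

    The model input carries the forget-gated coordinates (zeros where
    missing), the mask bits, and the interpolant baseline itself, so the
    recurrence sees both the raw evidence and the default it is correcting.
    Returns (X (T, 125), baseline (T, 50), center, scale, extrapolated).
    """
    center, scale = _window_stats(coords, mask)
    norm = (coords - center) / scale
    gated = np.where(mask.astype(bool)[:, :, None], norm, 0.0)  # forget-gated input
    base, extrapolated = _interp_baseline(norm, mask)
    base = base.reshape(len(coords), -1)
    X = np.concatenate(
        [gated.reshape(len(coords), -1), mask.astype(float), base], axis=1
    )
    return X, base, center, scale, extrapolated


# ---- inference -----------------------------------------------------------


def _window_assignment(T: int, W: int) -> tuple[np.ndarray, np.ndarray]:
    """Window starts and the per-frame source-window index (most central)."""
    if T <= W:
        return np.array([0]), np.zeros(T, dtype=int)
    stride = max(W // 2, 1)
    starts = np.arange(0, T - W, stride)
    starts = np.append(starts, T - W)
    t = np.arange(T)
    centers = starts[:, None] + W / 2.0
    widx = np.abs(centers - t[None, :]).argmin(axis=0)
    return starts, widx


def repair_forward(model: RepairModel, seq: KeypointSequence) -> KeypointSequence:
    """Impute the missing joints of a sequence; pass observed ones through.

    Observed coordinates are returned bit-identically.  Missing joints are
    replaced by the model's window-local prediction; the output mask is all
    ones and ``flags`` records per-joint provenance ("observed", "imputed",
    or "extrapolated" for one-sided boundary context).

    Raises :class:`RepairError` if the sequence is empty, has fewer than two
    frames with any observation, or contains a joint that is missing in
    every frame (nothing anchors its trajectory).
    """
    if seq.n_frames == 0:
        raise RepairError("empty sequence")
    obs = seq.mask.astype(bool)
    if int(obs.any(axis=1).sum()) < 2:
        raise RepairError("need at least 2 frames with observed joints")
    never = np.flatnonzero(~obs.any(axis=0))
    if never.size:
        raise RepairError(
            f"joint(s) {never.tolist()} are missing in every frame and cannot "
            "be repaired from temporal context"
        )

    out = seq.copy()
    T = seq.n_frames
    flags = np.where(obs, FLAG_OBSERVED, FLAG_IMPUTED).astype(object)
    if obs.all():
        out.flags = flags
        return out

    # inference windows match the training crop length; the memory horizon
    # stays a hard upper bound on how far context can reach
    W = min(model.config.train_window, model.config.memory_horizon, T)
    starts, widx = _window_assignment(T, W)
    Xs, bases, centers, scales, extras = [], [], [], [], []
    for s0 in starts:
        X, base, center, scale, extra = _prepare_window(
            seq.coords[s0:s0 + W], seq.mask[s0:s0 + W]
        )
        Xs.append(X)
        bases.append(base)
        centers.append(center)
        scales.append(scale)
        extras.append(extra)
    preds = model.predict_windows(np.stack(Xs), np.stack(bases))  # (nW, W, 50)

    for t in range(T):
        wi = widx[t]
        local_t = t - starts[wi]
        miss = ~obs[t]
        if not miss.any():
            continue
        pred = preds[wi, local_t].reshape(N_JOINTS, 2) * scales[wi] + centers[wi]
        out.coords[t, miss] = pred[miss]
        out.conf[t, miss] = 1.0
        flags[t, miss & extras[wi][local_t]] = FLAG_EXTRAPOLATED
    out.mask = np.ones_like(seq.mask)
    out.flags = flags
    return out


def linear_interpolation_repair(seq: KeypointSequence) -> KeypointSequence:
    """Per-joint linear-interpolation baseline with the same contract."""
    model = RepairModel(RepairConfig(hidden_size=2, bidirectional=False))
    # W_out is zero-initialized, so the model's output IS the interpolant.
    return repair_forward(model, seq)


# ---- training ------------------------------------------------------------


def _prepare_pair(occluded: KeypointSequence, complete: KeypointSequence):
    """Window-ready arrays for one (occluded, complete) training pair."""
    if occluded.n_frames != complete.n_frames:
        raise ValueError("occluded and complete sequences must be frame-aligned")
    return occluded.coords, occluded.mask, complete.coords, complete.mask


def _make_crops(pairs, window: int, rng: np.random.Generator,
                crops_per_seq: int = 1) -> dict[int, list]:
    """Random window crops per sequence, grouped by length for batching.

    The loss mask is restricted to the frames inference would actually take
    from a window at this position: the central half for interior windows,
    plus the leading/trailing half when the crop touches a sequence
    boundary.  Without this restriction training is dominated by
    window-edge extrapolation cases whose predictions are never used.
    """
    crops: dict[int, list] = {}
    for coords_o, mask_o, coords_c, mask_c in pairs:
        T = coords_o.shape[0]
        L = min(window, T)
        for _ in range(crops_per_seq):
            s0 = int(rng.integers(0, T - L + 1))
            sl = slice(s0, s0 + L)
            X, base, center, scale, _ = _prepare_window(coords_o[sl], mask_o[sl])
            target = ((coords_c[sl] - center) / scale).reshape(L, -1)
            lmask = ((mask_o[sl] == 0) & (mask_c[sl] == 1)).astype(float)
            used = np.zeros(L)
            used[L // 4: L - L // 4] = 1.0
            if s0 == 0:
                used[: L // 2] = 1.0
            if s0 + L == T:
                used[L // 2:] = 1.0
            lmask = lmask * used[:, None]
            crops.setdefault(L, []).append((X, base, target, np.repeat(lmask, 2, axis=1)))
    return crops


def _probe_loss(model: RepairModel, crops: dict[int, list]) -> float:
    """Masked MSE of the current model on a fixed crop set (forward only)."""
    sq_sum = 0.0
    n = 0.0
    for items in crops.values():
        X = np.stack([it[0] for it in items])
        base = np.stack([it[1] for it in items])
        target = np.stack([it[2] for it in items])
        lmask = np.stack([it[3] for it in items])
        pred = model.predict_windows(X, base)
        sq_sum += float((((pred - target) * lmask) ** 2).sum())
        n += float(lmask.sum())
    return sq_sum / n if n else 0.0


def train_repair(
    config: RepairConfig,
    dataset: Sequence[tuple[KeypointSequence, KeypointSequence]],
    epochs: int | None = None,
    batch_size: int | None = None,
    seed: int | None = None,
) -> tuple[RepairModel, list[float]]:
    """Fit the repair model on (occluded, complete) sequence pairs.

    The loss is mean squared coordinate error *on masked positions only*
    (observed joints are pass-through by contract, so there is nothing to
    learn about them), in window-normalized units.  Each epoch crops one
    random window of ``config.train_window`` frames per sequence and
    optimizes with Adam (default) or gradient descent with momentum, plus
    weight decay and global gradient-norm clipping.  Deterministic given
    the seed.  Returns the
    model and the per-epoch loss history (empty when ``epochs == 0``);
    the history is evaluated after each epoch on a fixed probe set of
    crops so it tracks model progress rather than crop-sampling noise.
    """
    if not dataset:
        raise ValueError("dataset must be nonempty")
    epochs = config.epochs if epochs is None else epochs
    batch_size = config.batch_size if batch_size is None else batch_size
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    model = RepairModel(config, rng=np.random.default_rng(int(rng.integers(2 ** 31))))
    pairs = [_prepare_pair(occ, comp) for occ, comp in dataset]

    opt_m = {k: np.zeros_like(v) for k, v in model.params.items()}
    opt_v = {k: np.zeros_like(v) for k, v in model.params.items()}
    step = 0
    history: list[float] = []
    Wl = config.train_window
    probe = _make_crops(pairs, Wl, np.random.default_rng(int(rng.integers(2 ** 31))),
                        crops_per_seq=2)
    for _epoch in range(epochs):
        lr = config.learning_rate * config.lr_decay ** _epoch
        # fresh random crops each epoch (data augmentation over window phase)
        crops = _make_crops(pairs, Wl, rng, crops_per_seq=config.crops_per_seq)
        for L, items in crops.items():
            rng.shuffle(items)
            for b0 in range(0, len(items), batch_size):
                batch = items[b0:b0 + batch_size]
                X = np.stack([it[0] for it in batch])
                base = np.stack([it[1] for it in batch])
                target = np.stack([it[2] for it in batch])
                lmask = np.stack([it[3] for it in batch])
                n_masked = lmask.sum()
                if n_masked == 0:
                    continue
                Hcat, caches = model.hidden_states(X)
                pred = Hcat @ model.params["W_out"] + model.params["b_out"] + base
                diff = (pred - target) * lmask
                loss = float((diff ** 2).sum() / n_masked)
                if not math.isfinite(loss):
                    raise TrainingError(
                        f"repair training diverged at epoch {_epoch}: loss is not finite"
                    )

                dpred = 2.0 * diff / n_masked
                grads = {}
                B, Lw, _ = X.shape
                Hflat = Hcat.reshape(B * Lw, -1)
                dflat = dpred.reshape(B * Lw, -1)
                grads["W_out"] = Hflat.T @ dflat
                grads["b_out"] = dflat.sum(axis=0)
                dHcat = dpred @ model.params["W_out"].T
                H = config.hidden_size
                dWx, dWh, db = _lstm_backward(
                    dHcat[:, :, :H], caches["f"], model.params["Wx_f"], model.params["Wh_f"]
                )
                grads["Wx_f"], grads["Wh_f"], grads["b_f"] = dWx, dWh, db
                if config.bidirectional:
                    dWx, dWh, db = _lstm_backward(
                        dHcat[:, ::-1, H:], caches["b"],
                        model.params["Wx_b"], model.params["Wh_b"],
                    )
                    grads["Wx_b"], grads["Wh_b"], grads["b_b"] = dWx, dWh, db

                # weight decay on matrices, global-norm clip, optimizer step
                for k in grads:
                    if k.startswith("W"):
                        grads[k] = grads[k] + config.weight_decay * model.params[k]
                gnorm = math.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
                if gnorm > config.grad_clip:
                    for k in grads:
                        grads[k] = grads[k] * (config.grad_clip / gnorm)
                step += 1
                for k, g in grads.items():
                    if config.optimizer == "adam":
                        opt_m[k] = 0.9 * opt_m[k] + 0.1 * g
                        opt_v[k] = 0.999 * opt_v[k] + 0.001 * g * g
                        mhat = opt_m[k] / (1 - 0.9 ** step)
                        vhat = opt_v[k] / (1 - 0.999 ** step)
                        model.params[k] = model.params[k] - (
                            lr * mhat / (np.sqrt(vhat) + 1e-8)
                        )
                    else:
                        opt_m[k] = config.momentum * opt_m[k] - lr * g
                        model.params[k] = model.params[k] + opt_m[k]
        history.append(_probe_loss(model, probe))
    return model, history


def masked_rmse(
    repaired: KeypointSequence,
    complete: KeypointSequence,
    mask_missing: np.ndarray,
) -> float:
    """Pixel RMSE of repaired coordinates over the given missing positions."""
    sel = mask_missing.astype(bool)
    if not sel.any():
        return 0.0
    d = repaired.coords[sel] - complete.coords[sel]
    return float(np.sqrt((d ** 2).sum(axis=1).mean()))
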