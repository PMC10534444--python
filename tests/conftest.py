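"""Shared fixtures: synthetic datasets and trained models.

The expensive fixtures (trained repair model, trained lifter) are
session-scoped so the benchmark suite trains each model once.  All sizes
and seeds are frozen here; they define the synthetic study conditions the
benchmarks run under.
"""

from __future__ import annotations

import numpy as np
import pytest

import fallhic as fh


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small stratified fall set for fast unit tests."""
    return fh.make_dataset(12, seed=11)


@pytest.fixture(scope="session")
def repair_benchmark():
    """Train the imputer under the benchmark conditions and evaluate it.

    200 stratified falls at 20% burst occlusion (dataset seed 7), training
    seed 0; masked-joint pixel RMSE of the trained model and of the
    per-joint linear-interpolation baseline on the validation split.
    """
    splits = fh.make_dataset(200, seed=7)
    pairs = [(c.occluded2d, c.clean2d) for c in splits.train]
    cfg = fh.RepairConfig(hidden_size=64, epochs=80,
                          train_window=64, memory_horizon=64)
    model, history = fh.train_repair(cfg, pairs, seed=0)
    model_rmse, interp_rmse = [], []
    for clip in splits.validation:
        missing = (clip.occluded2d.mask == 0) & (clip.clean2d.mask == 1)
        repaired = fh.repair_forward(model, clip.occluded2d)
        baseline = fh.linear_interpolation_repair(clip.occluded2d)
        model_rmse.append(fh.masked_rmse(repaired, clip.clean2d, missing))
        interp_rmse.append(fh.masked_rmse(baseline, clip.clean2d, missing))
    return {
        "splits": splits,
        "model": model,
        "history": history,
        "model_rmse": float(np.mean(model_rmse)),
        "interp_rmse": float(np.mean(interp_rmse)),
    }


@pytest.fixture(scope="session")
def lifter_benchmark():
    """Train the lifter on 5000 synthetic frames and evaluate it.

    60 stratified falls (seed 11); 5000 frames subsampled from the training
    split; validation error compared against the mean-training-pose
    baseline.
    """
    splits = fh.make_dataset(60, seed=11)
    X, Y = fh.make_lifting_dataset(
        [(c.clean2d, c.truth.pose3d) for c in splits.train]
    )
    idx = np.random.default_rng(0).permutation(X.shape[0])[:5000]
    Xtr, Ytr = X[idx], Y[idx]
    model, history = fh.train_lifter(fh.LifterConfig(epochs=15), Xtr, Ytr, seed=0)
    Xv, Yv = fh.make_lifting_dataset(
        [(c.clean2d, c.truth.pose3d) for c in splits.validation]
    )
    err = fh.mean_per_joint_error(model.predict(Xv), Yv)
    baseline = fh.mean_per_joint_error(
        np.tile(Ytr.mean(axis=0), (Yv.shape[0], 1)), Yv
    )
    return {
        "splits": splits,
        "model": model,
        "history": history,
        "error": err,
        "baseline": baseline,
    }


@pytest.fixture()
def simple_sequence():
    """A clean, fully observed 2D sequence from one simulated fall."""
    scenario = fh.FallScenario(drop_height=0.5, impact_omega=200.0, seed=3)
    truth = fh.simulate_fall(scenario)
    return fh.project_to_camera(truth.pose3d, scenario.camera)
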