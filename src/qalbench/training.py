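"""Variational training of the quantum classifier.

Training minimises the mean binary cross-entropy of the parity-decoded
class probability over a stratified 70/30 train split, with parameters
initialised uniformly in [-pi, pi].  Each configuration is trained over
``n_runs`` independent seeded runs and the final losses are aggregated
as mean +/- sample standard deviation, mirroring the multi-run protocol
used to tame the stochasticity of noisy circuit evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import MODEL_FACTORS
from .optimizers import OptimizerConfig, TrainRun, minimize
from .qnn import QNNClassifier
from .simulator import SimConfig

__all__ = [
    "TrainConfig",
    "TrainResult",
    "bce_loss",
    "stratified_split",
    "train_qnn",
]

_CLIP = 1e-12


def bce_loss(probabilities, labels) -> float:
    """Mean binary cross-entropy with probabilities clipped away from 0/1."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels length mismatch")
    p = np.clip(p, _CLIP, 1.0 - _CLIP)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


@dataclass(frozen=True)
class TrainConfig:
    ansatz_kind: str = "efficient_su2"
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    n_runs: int = 10
    sim: SimConfig = field(default_factory=SimConfig)
    features: tuple[str, ...] = MODEL_FACTORS
    outcome: str = "LEAK"
    test_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass(frozen=True)
class TrainResult:
    runs: tuple[TrainRun, ...]
    mean_final_loss: float
    std_final_loss: float
    train_index: np.ndarray
    test_index: np.ndarray


def stratified_split(
    y, test_fraction: float = 0.3, rng: np.random.Generator | int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Index split preserving the class balance within rounding."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    y = np.asarray(y)
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_test = int(round(len(idx) * test_fraction))
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def make_objective(clf: QNNClassifier, X: np.ndarray, y: np.ndarray, seed=None):
    """BCE objective over a dataset; stochastic when shots are finite.

    The objective re-evaluates the circuit on every call (no caching of
    loss values), so finite-shot noise enters each evaluation afresh.
    """
    counter = {"calls": 0}

    def objective(params):
        counter["calls"] += 1
        rng = (
            np.random.default_rng((seed, counter["calls"]))
            if clf.config.shots is not None
            else None
        )
        p = clf.predict_proba(params, X, rng=rng)
        return bce_loss(p, y)

    return objective


def train_qnn(
    cohort: pd.DataFrame, config: TrainConfig, split=None
) -> TrainResult:
    """Train one ansatz/optimizer pair over ``config.n_runs`` seeded runs.

    ``split`` may carry precomputed (train_index, test_index) so several
    models can share one evaluation split; otherwise a stratified split
    is drawn from ``config.seed``.
    """
    missing = [c for c in (*config.features, config.outcome) if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks columns {missing}")
    X = cohort[list(config.features)].to_numpy(dtype=float)
    y = cohort[config.outcome].to_numpy(dtype=float)
    ss = np.random.SeedSequence(config.seed)
    if split is None:
        split_rng = np.random.default_rng(ss.spawn(1)[0])
        train_idx, test_idx = stratified_split(y, config.test_fraction, split_rng)
    else:
        train_idx, test_idx = (np.asarray(s, dtype=int) for s in split)

    runs = []
    for r, child in enumerate(ss.spawn(config.n_runs + 1)[1:]):
        run_seed = int(child.generate_state(1)[0] % (2 ** 31))
        rng = np.random.default_rng(run_seed)
        clf = QNNClassifier(
            ansatz_kind=config.ansatz_kind,
            n_features=len(config.features),
            config=config.sim,
        )
        objective = make_objective(clf, X[train_idx], y[train_idx], seed=run_seed)
        x0 = rng.uniform(-np.pi, np.pi, size=clf.n_params)
        opt = replace(config.optimizer, seed=run_seed)
        runs.append(minimize(objective, x0, opt))

    finals = np.array([r.final_loss for r in runs])
    return TrainResult(
        runs=tuple(runs),
        mean_final_loss=float(finals.mean()),
        std_final_loss=float(finals.std()),  # population sd over the runs
        train_index=train_idx,
        test_index=test_idx,
    )
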