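"""Perturbation-based feature importance for opaque classifiers.

Two complementary probes of a fitted ``predict_fn``:

* permutation importance — shuffle one feature column at a time (a fresh
  permutation per repeat, 100 repeats by default) and record the mean
  drop in test AUC; a model that leans on a feature loses discrimination
  when that feature's link to the outcome is broken;
* gradient importance — add a minute perturbation epsilon to one feature
  at a time and record the mean absolute change in predicted
  probability, a finite-difference reading of the model's local
  sensitivity.

Raw scores are normalised to sum to one (negative mean AUC drops are
clipped at zero first) so the per-feature scores form a distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import roc_auc

__all__ = ["ImportanceConfig", "ImportanceReport", "permutation_importance", "gradient_importance"]


@dataclass(frozen=True)
class ImportanceConfig:
    n_repeats: int = 100
    epsilon: float = 1e-2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass(frozen=True)
class ImportanceReport:
    method: str
    feature_names: tuple[str, ...]
    raw: np.ndarray
    normalized: np.ndarray
    baseline: float

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {
            name: {"raw": float(r), "normalized": float(s)}
            for name, r, s in zip(self.feature_names, self.raw, self.normalized)
        }


def _normalise(raw: np.ndarray, clip: bool) -> np.ndarray:
    """Scores as a distribution; NaN when no feature carries signal and
    the caller tolerates that (clipped permutation drops), else an error.
    """
    scores = np.clip(raw, 0.0, None) if clip else np.abs(raw)
    total = scores.sum()
    if total <= 0:
        if clip:
            return np.full_like(scores, np.nan)
        raise ValueError("all importance scores are zero: nothing to normalise")
    return scores / total


def _names(X, feature_names):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if feature_names is None:
        feature_names = tuple(f"x{i}" for i in range(X.shape[1]))
    return X, tuple(feature_names)


def permutation_importance(
    predict_fn, X, y, config: ImportanceConfig | None = None, feature_names=None
) -> ImportanceReport:
    """Mean AUC decrease when each feature is shuffled across samples."""
    if config is None:
        config = ImportanceConfig()
    X, feature_names = _names(X, feature_names)
    y = np.asarray(y, dtype=float).ravel()
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    rng = np.random.default_rng(config.seed)
    baseline = roc_auc(y, predict_fn(X))
    raw = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        drops = np.empty(config.n_repeats)
        for r in range(config.n_repeats):
            Xp = X.copy()
            Xp[:, j] = X[rng.permutation(X.shape[0]), j]
            drops[r] = baseline - roc_auc(y, predict_fn(Xp))
        raw[j] = drops.mean()
    return ImportanceReport(
        method="permutation",
        feature_names=feature_names,
        raw=raw,
        normalized=_normalise(raw, clip=True),
        baseline=float(baseline),
    )


def gradient_importance(
    predict_fn, X, config: ImportanceConfig | None = None, feature_names=None
) -> ImportanceReport:
    """Mean absolute probability change under a perturbation of size
    epsilon applied to each raw feature (before any encoding)."""
    if config is None:
        config = ImportanceConfig()
    X, feature_names = _names(X, feature_names)
    base = np.asarray(predict_fn(X), dtype=float)
    if not np.all(np.isfinite(base)):
        raise ValueError("predict_fn returned non-finite values")
    raw = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        Xp = X.copy()
        Xp[:, j] = Xp[:, j] + config.epsilon
        pert = np.asarray(predict_fn(Xp), dtype=float)
        if not np.all(np.isfinite(pert)):
            raise ValueError("predict_fn returned non-finite values")
        raw[j] = float(np.mean(np.abs(pert - base)))
    return ImportanceReport(
        method="gradient",
        feature_names=feature_names,
        raw=raw,
        normalized=_normalise(raw, clip=False),
        baseline=float(np.mean(base)),
    )
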