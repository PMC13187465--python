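"""Native classical baseline classifiers.

All five baselines are implemented directly at fixed, documented
settings and expose ``predict_proba(X) -> P(class 1)``:

* LR — the package's own IRLS logistic fit;
* LDA — shared-covariance Gaussian classes, closed form;
* GNB — per-feature Gaussian class conditionals with a variance floor;
* AdaBoost — depth-1 decision stumps with exponential-loss weights,
  probabilities via the logistic of the ensemble margin;
* MLP — one hidden layer (8 logistic units) trained on binary
  cross-entropy by full-batch gradient descent with seeded init.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .logistic import fit_logistic

__all__ = ["BASELINES", "fit_classical_baseline"]

BASELINES = ("LR", "LDA", "GNB", "AdaBoostStumps", "MLP")


def _validate(X, y):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y length mismatch")
    if y.min() == y.max():
        raise ValueError("y must contain both classes")
    return X, y


@dataclass
class _LRBaseline:
    fit_: object = None

    def fit(self, X, y):
        X, y = _validate(X, y)
        self.fit_ = fit_logistic(X, y)
        return self

    def predict_proba(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.fit_.model.predict_proba(X, list(self.fit_.names))


@dataclass
class _LDABaseline:
    """Two-class linear discriminant with pooled covariance."""

    def fit(self, X, y):
        X, y = _validate(X, y)
        self.pi1_ = y.mean()
        self.mu0_ = X[y == 0].mean(axis=0)
        self.mu1_ = X[y == 1].mean(axis=0)
        n = len(y)
        cov = np.zeros((X.shape[1], X.shape[1]))
        for cls, mu in ((0, self.mu0_), (1, self.mu1_)):
            d = X[y == cls] - mu
            cov += d.T @ d
        cov /= max(n - 2, 1)
        cov += 1e-9 * np.eye(X.shape[1])
        prec = np.linalg.inv(cov)
        self.w_ = prec @ (self.mu1_ - self.mu0_)
        self.b_ = (
            -0.5 * (self.mu1_ @ prec @ self.mu1_ - self.mu0_ @ prec @ self.mu0_)
            + np.log(self.pi1_ / (1 - self.pi1_))
        )
        return self

    def predict_proba(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return expit(X @ self.w_ + self.b_)


@dataclass
class _GNBBaseline:
    """Gaussian naive Bayes with a 1e-9 variance floor."""

    var_floor: float = 1e-9

    def fit(self, X, y):
        X, y = _validate(X, y)
        self.log_prior_ = np.log([1 - y.mean(), y.mean()])
        self.mu_ = np.stack([X[y == c].mean(axis=0) for c in (0, 1)])
        self.var_ = np.maximum(
            np.stack([X[y == c].var(axis=0) for c in (0, 1)]), self.var_floor
        )
        return self

    def _joint_ll(self, X):
        out = np.empty((X.shape[0], 2))
        for c in (0, 1):
            out[:, c] = self.log_prior_[c] - 0.5 * np.sum(
                np.log(2 * np.pi * self.var_[c])
                + (X - self.mu_[c]) ** 2 / self.var_[c],
                axis=1,
            )
        return out

    def predict_proba(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        ll = self._joint_ll(X)
        return expit(ll[:, 1] - ll[:, 0])


@dataclass
class _Stump:
    feature: int
    threshold: float
    polarity: int  # +1: predict +1 when x >= t

    def predict(self, X):
        pred = np.where(X[:, self.feature] >= self.threshold, 1.0, -1.0)
        return self.polarity * pred


@dataclass
class _AdaBoostStumps:
    """AdaBoost with depth-1 stumps and standard exponential-loss updates."""

    n_rounds: int = 50

    def fit(self, X, y):
        X, y = _validate(X, y)
        yy = 2.0 * y - 1.0
        n = len(y)
        w = np.full(n, 1.0 / n)
        self.stumps_: list[_Stump] = []
        self.alphas_: list[float] = []
        for _ in range(self.n_rounds):
            stump, err = self._best_stump(X, yy, w)
            err = min(max(err, 1e-10), 1 - 1e-10)
            alpha = 0.5 * np.log((1 - err) / err)
            pred = stump.predict(X)
            w = w * np.exp(-alpha * yy * pred)
            w /= w.sum()
            self.stumps_.append(stump)
            self.alphas_.append(float(alpha))
            if err < 1e-9:
                break
        return self

    @staticmethod
    def _best_stump(X, yy, w):
        best, best_err = None, np.inf
        for j in range(X.shape[1]):
            values = np.unique(X[:, j])
            cuts = np.concatenate([[values[0] - 1.0], (values[:-1] + values[1:]) / 2.0, [values[-1] + 1.0]])
            for t in cuts:
                base = np.where(X[:, j] >= t, 1.0, -1.0)
                for pol in (1, -1):
                    err = float(np.sum(w[pol * base != yy]))
                    if err < best_err:
                        best_err = err
                        best = _Stump(j, float(t), pol)
        return best, best_err

    def margin(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        acc = np.zeros(X.shape[0])
        for stump, alpha in zip(self.stumps_, self.alphas_):
            acc += alpha * stump.predict(X)
        return acc

    def predict_proba(self, X):
        # logistic link on the ensemble margin (Friedman's 2F(x) mapping)
        return expit(2.0 * self.margin(X))


@dataclass
class _MLPBaseline:
    """One hidden layer of logistic units, full-batch gradient descent on BCE."""

    hidden: int = 8
    lr: float = 0.5
    n_epochs: int = 2000
    seed: int = 0
    l2: float = 1e-4

    def fit(self, X, y):
        X, y = _validate(X, y)
        rng = np.random.default_rng(self.seed)
        n, d = X.shape
        self.W1_ = rng.normal(0, 1.0 / np.sqrt(d), (d, self.hidden))
        self.b1_ = np.zeros(self.hidden)
        self.W2_ = rng.normal(0, 1.0 / np.sqrt(self.hidden), self.hidden)
        self.b2_ = 0.0
        for _ in range(self.n_epochs):
            h = expit(X @ self.W1_ + self.b1_)
            p = expit(h @ self.W2_ + self.b2_)
            delta = (p - y) / n
            gW2 = h.T @ delta + self.l2 * self.W2_
            gb2 = delta.sum()
            dh = np.outer(delta, self.W2_) * h * (1 - h)
            gW1 = X.T @ dh + self.l2 * self.W1_
            gb1 = dh.sum(axis=0)
            self.W2_ -= self.lr * gW2
            self.b2_ -= self.lr * gb2
            self.W1_ -= self.lr * gW1
            self.b1_ -= self.lr * gb1
        return self

    def predict_proba(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        h = expit(X @ self.W1_ + self.b1_)
        return expit(h @ self.W2_ + self.b2_)


_REGISTRY = {
    "LR": _LRBaseline,
    "LDA": _LDABaseline,
    "GNB": _GNBBaseline,
    "ADABOOSTSTUMPS": _AdaBoostStumps,
    "ADABOOST": _AdaBoostStumps,
    "MLP": _MLPBaseline,
}


def fit_classical_baseline(kind: str, X, y, **kwargs):
    """Fit one named baseline; returns an object with ``predict_proba``."""
    cls = _REGISTRY.get(kind.upper().replace("-", "").replace("_", ""))
    if cls is None:
        raise ValueError(f"unknown baseline kind {kind!r}")
    return cls(**kwargs).fit(X, y)
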