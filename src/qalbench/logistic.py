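"""Multivariate logistic regression with Wald inference, information
criteria, likelihood-ratio tests and backward stepwise selection.

The fitter is a plain Newton/IRLS maximiser of the Bernoulli
log-likelihood with a tiny ridge jitter (1e-8) on the information matrix
for near-separation stability.  ``k`` counts the intercept, so
AIC = 2k - 2*loglik and BIC = k*ln(n) - 2*loglik.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm

__all__ = [
    "LogisticModel",
    "LogisticFit",
    "SelectionReport",
    "SeparationError",
    "fit_logistic",
    "information_criteria",
    "likelihood_ratio_test",
    "stepwise_select",
    "odds_ratios",
]


class SeparationError(RuntimeError):
    """Likelihood diverges: (quasi-)complete separation."""


@dataclass(frozen=True)
class LogisticModel:
    """Coefficients of a logistic model, slopes keyed by covariate name.

    ``coding`` records the indicator convention of the covariates
    ("protective" = 1 is the protective state, so the risky-vs-protective
    odds ratio is exp(|beta|) when beta < 0).
    """

    intercept: float
    slopes: dict[str, float] = field(default_factory=dict)
    coding: str = "protective"

    def linear_predictor(self, X: np.ndarray, names: list[str] | None = None) -> np.ndarray:
        names = list(self.slopes) if names is None else names
        beta = np.array([self.slopes[c] for c in names])
        return self.intercept + np.asarray(X, float) @ beta

    def predict_proba(self, X: np.ndarray, names: list[str] | None = None) -> np.ndarray:
        return expit(self.linear_predictor(X, names))


@dataclass(frozen=True)
class LogisticFit:
    model: LogisticModel
    names: tuple[str, ...]
    se: np.ndarray              # (k,) incl. intercept first
    cov: np.ndarray             # (k, k)
    loglik: float
    n: int
    k: int                      # estimated coefficients, intercept included
    converged: bool
    wald_z: np.ndarray = field(default=None)  # type: ignore[assignment]
    wald_p: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def coef(self) -> np.ndarray:
        return np.concatenate(
            [[self.model.intercept], [self.model.slopes[c] for c in self.names]]
        )


def _design(X, names=None):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if names is None:
            names = [f"x{i}" for i in range(X.shape[1])]
    return X, list(names)


def _loglik(y, eta):
    # numerically safe sum of y*eta - log(1 + exp(eta))
    return float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))


def fit_logistic(
    X,
    y,
    tol: float = 1e-10,
    max_iter: int = 100,
    ridge: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    Convergence is declared when the log-likelihood change drops below
    ``tol``.  Complete separation (coefficients running away) raises
    :class:`SeparationError`; a constant outcome is rejected up front.
    """
    X, names = _design(X)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y length mismatch")
    if y.min() == y.max():
        raise ValueError("y must contain both classes")
    Xd = np.column_stack([np.ones(len(y)), X])
    k = Xd.shape[1]
    beta = np.zeros(k)
    ll = _loglik(y, Xd @ beta)
    converged = False
    for _ in range(max_iter):
        eta = Xd @ beta
        p = expit(eta)
        w = p * (1.0 - p)
        info = Xd.T @ (Xd * w[:, None]) + ridge * np.eye(k)
        grad = Xd.T @ (y - p)
        step = np.linalg.solve(info, grad)
        # damped Newton: halve until the likelihood does not decrease
        scale = 1.0
        for _ in range(30):
            new_ll = _loglik(y, Xd @ (beta + scale * step))
            if new_ll >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        if np.max(np.abs(beta)) > 40.0:
            raise SeparationError("coefficients diverge: data are separated")
        if abs(new_ll - ll) < tol:
            ll = new_ll
            converged = True
            break
        ll = new_ll

    p = expit(Xd @ beta)
    w = p * (1.0 - p)
    info = Xd.T @ (Xd * w[:, None]) + ridge * np.eye(k)
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * norm.sf(np.abs(z))
    model = LogisticModel(
        intercept=float(beta[0]),
        slopes={c: float(b) for c, b in zip(names, beta[1:])},
    )
    return LogisticFit(
        model=model,
        names=tuple(names),
        se=se,
        cov=cov,
        loglik=ll,
        n=len(y),
        k=k,
        converged=converged,
        wald_z=z,
        wald_p=pvals,
    )


def information_criteria(fit: LogisticFit | None = None, *, loglik=None, k=None, n=None):
    """(AIC, BIC) with the intercept counted in k."""
    if fit is not None:
        loglik, k, n = fit.loglik, fit.k, fit.n
    aic = 2.0 * k - 2.0 * loglik
    bic = (k * np.log(n) if n else 0.0) - 2.0 * loglik
    return float(aic), float(bic)


def likelihood_ratio_test(nested: LogisticFit, full: LogisticFit) -> tuple[float, int, float]:
    """LR chi-square test of a nested model against a richer one.

    Returns (statistic, df, p).  Covariates of the nested model must be a
    subset of the full model's and both must be fitted to the same data.
    """
    if not set(nested.names) <= set(full.names):
        raise ValueError("models are not nested")
    if nested.n != full.n:
        raise ValueError("fits use different data")
    stat = 2.0 * (full.loglik - nested.loglik)
    df = full.k - nested.k
    if df == 0:
        return max(stat, 0.0), 0, 1.0
    return float(max(stat, 0.0)), df, float(chi2.sf(max(stat, 0.0), df))


@dataclass(frozen=True)
class SelectionReport:
    criterion: str
    visited: tuple[tuple[tuple[str, ...], float], ...]
    selected: tuple[str, ...]
    fit: LogisticFit


def stepwise_select(X, y, criterion: str = "AIC") -> SelectionReport:
    """Backward elimination on AIC or BIC.

    Starts from the full model and repeatedly removes the covariate whose
    removal most improves the criterion, stopping when no removal improves
    it (the empty, intercept-only model is a candidate endpoint).
    """
    criterion = criterion.upper()
    if criterion not in ("AIC", "BIC"):
        raise ValueError("criterion must be 'AIC' or 'BIC'")
    X, names = _design(X)
    frame = pd.DataFrame(X, columns=names)
    idx = 0 if criterion == "AIC" else 1

    def score(cols: tuple[str, ...]) -> tuple[float, LogisticFit]:
        if cols:
            f = fit_logistic(frame[list(cols)], y)
        else:
            f = _intercept_only_fit(y)
        return information_criteria(f)[idx], f

    current = tuple(names)
    cur_score, cur_fit = score(current)
    visited = [(current, cur_score)]
    while current:
        candidates = []
        for drop in current:
            cols = tuple(c for c in current if c != drop)
            s, f = score(cols)
            candidates.append((s, cols, f))
            visited.append((cols, s))
        best = min(candidates, key=lambda t: t[0])
        if best[0] < cur_score:
            cur_score, current, cur_fit = best[0], best[1], best[2]
        else:
            break
    return SelectionReport(
        criterion=criterion,
        visited=tuple(visited),
        selected=current,
        fit=cur_fit,
    )


def _intercept_only_fit(y) -> LogisticFit:
    y = np.asarray(y, dtype=float).ravel()
    pbar = y.mean()
    if pbar in (0.0, 1.0):
        raise ValueError("y must contain both classes")
    b0 = float(np.log(pbar / (1 - pbar)))
    ll = _loglik(y, np.full(len(y), b0))
    se = np.array([1.0 / np.sqrt(len(y) * pbar * (1 - pbar))])
    return LogisticFit(
        model=LogisticModel(intercept=b0, slopes={}),
        names=(),
        se=se,
        cov=se[:, None] ** 2,
        loglik=ll,
        n=len(y),
        k=1,
        converged=True,
        wald_z=np.array([b0]) / se,
        wald_p=2.0 * norm.sf(np.abs(np.array([b0]) / se)),
    )


def intercept_only_loglik(y) -> float:
    """Null-model log-likelihood, used by pseudo-R-squared measures."""
    return _intercept_only_fit(y).loglik


def odds_ratios(model: LogisticModel, se: dict[str, float] | None = None, z: float = 1.96):
    """Risky-vs-protective odds ratio per covariate.

    Under the protective coding the riskier category is the 0 state for
    every indicator, so OR = exp(|beta|).  With standard errors available,
    a Wald CI exp(|beta| +/- z*se) is attached; otherwise point estimates
    only.
    """
    out: dict[str, dict[str, float]] = {}
    for name, beta in model.slopes.items():
        entry = {"or": float(np.exp(abs(beta)))}
        if se is not None and name in se:
            entry["ci_low"] = float(np.exp(abs(beta) - z * se[name]))
            entry["ci_high"] = float(np.exp(abs(beta) + z * se[name]))
        out[name] = entry
    return out
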