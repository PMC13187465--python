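"""Discrimination, calibration, pseudo-R-squared and fixed-sensitivity
threshold metrics, with multi-run aggregation.

The clinical benchmark fixes sensitivity at 83% and, among thresholds
reaching it, picks the one maximising an F-beta score (beta = 2 by
default, weighting recall four times precision).  Count R-squared is
defined as accuracy at that operating threshold; degenerate metrics are
reported as NaN ("undefined"), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logit
from scipy.stats import rankdata

from .logistic import intercept_only_loglik
from .training import bce_loss

__all__ = [
    "ThresholdPolicy",
    "MetricsReport",
    "roc_auc",
    "average_precision",
    "calibration_metrics",
    "fbeta",
    "threshold_at_sensitivity",
    "classification_report",
    "aggregate_runs",
]


@dataclass(frozen=True)
class ThresholdPolicy:
    target_sensitivity: float = 0.83
    beta: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_sensitivity <= 1.0:
            raise ValueError("target sensitivity must lie in (0, 1]")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


def _check(labels, scores):
    y = np.asarray(labels, dtype=float).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if y.shape != s.shape:
        raise ValueError("labels and scores length mismatch")
    return y, s


def roc_auc(labels, scores) -> float:
    """P(random positive outranks random negative), ties counted half."""
    y, s = _check(labels, scores)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)  # midranks handle ties
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def average_precision(labels, scores) -> float:
    """Area under the precision-recall curve via recall-increment sums."""
    y, s = _check(labels, scores)
    n_pos = y.sum()
    if n_pos == 0:
        raise ValueError("no positives")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    precision = tp / np.arange(1, y.size + 1)
    recall = tp / n_pos
    # evaluate at distinct-score boundaries only (ties form one operating point)
    boundary = np.append(s_sorted[1:] != s_sorted[:-1], True)
    precision, recall = precision[boundary], recall[boundary]
    prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev) * precision))


def calibration_metrics(labels, probabilities) -> tuple[float, float]:
    """(Brier score, log loss)."""
    y, p = _check(labels, probabilities)
    brier = float(np.mean((y - p) ** 2))
    return brier, bce_loss(p, y)


def _confusion(y, p, threshold):
    pred = p >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    return tp, fp, fn, tn


def fbeta(precision: float, recall: float, beta: float) -> float:
    if np.isnan(precision) or precision + recall == 0:
        return 0.0
    b2 = beta * beta
    return float((1 + b2) * precision * recall / (b2 * precision + recall))


def threshold_at_sensitivity(labels, scores, policy: ThresholdPolicy | None = None) -> float:
    """Operating threshold for the fixed-sensitivity protocol.

    Candidates are the distinct score values (classification rule
    ``score >= threshold``).  Among candidates with sensitivity at or
    above the target, the one maximising F-beta wins (ties: higher
    specificity, then higher threshold); if no candidate reaches the
    target, the threshold of maximal sensitivity wins with the same
    tie-breaks.
    """
    if policy is None:
        policy = ThresholdPolicy()
    y, s = _check(labels, scores)
    if y.sum() == 0:
        raise ValueError("no positives: sensitivity undefined")
    rows = []
    for t in np.unique(s):
        tp, fp, fn, tn = _confusion(y, s, t)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp) if tn + fp else 0.0
        prec = tp / (tp + fp) if tp + fp else np.nan
        rows.append((float(t), sens, spec, fbeta(prec, sens, policy.beta)))
    reaching = [r for r in rows if r[1] >= policy.target_sensitivity]
    if reaching:
        return max(reaching, key=lambda r: (r[3], r[2], r[0]))[0]
    return max(rows, key=lambda r: (r[1], r[2], r[0]))[0]


@dataclass(frozen=True)
class MetricsReport:
    threshold: float
    values: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.values[key]


_NAN = float("nan")


def classification_report(labels, probabilities, threshold: float) -> MetricsReport:
    """All benchmark metrics at one operating threshold.

    Rates with empty denominators come back NaN.  Pseudo-R-squared
    measures: Efron from squared residuals, McKelvey-Zavoina on the
    latent logit scale with residual variance pi^2/3, Count = accuracy at
    the threshold, McFadden / Cox-Snell / Nagelkerke from
    log-likelihoods.
    """
    y, p = _check(labels, probabilities)
    tp, fp, fn, tn = _confusion(y, p, threshold)
    n = y.size

    def rate(num, den):
        return num / den if den else _NAN

    recall = rate(tp, tp + fn)
    specificity = rate(tn, tn + fp)
    precision = rate(tp, tp + fp)
    npv = rate(tn, tn + fn)
    accuracy = rate(tp + tn, n)
    f1 = fbeta(precision, recall, 1.0) if not np.isnan(precision) else _NAN

    brier, log_loss = calibration_metrics(y, p)
    ll = -log_loss * n
    ll0 = intercept_only_loglik(y) if 0 < y.sum() < n else _NAN
    ybar = y.mean()
    ss_res = float(np.sum((y - p) ** 2))
    ss_tot = float(np.sum((y - ybar) ** 2))
    efron = 1.0 - ss_res / ss_tot if ss_tot > 0 else _NAN
    eta = logit(np.clip(p, 1e-12, 1 - 1e-12))
    var_eta = float(np.var(eta))
    mz = var_eta / (var_eta + np.pi ** 2 / 3.0)
    if np.isnan(ll0):
        mcfadden = cox_snell = nagelkerke = _NAN
    else:
        mcfadden = 1.0 - ll / ll0
        cox_snell = 1.0 - float(np.exp(2.0 * (ll0 - ll) / n))
        nagelkerke = cox_snell / (1.0 - float(np.exp(2.0 * ll0 / n)))

    values = {
        "auc": roc_auc(y, p) if 0 < y.sum() < n else _NAN,
        "average_precision": average_precision(y, p) if y.sum() else _NAN,
        "accuracy": accuracy,
        "recall": recall,
        "specificity": specificity,
        "precision": precision,
        "ppv": precision,
        "npv": npv,
        "f1": f1,
        "brier": brier,
        "log_loss": log_loss,
        "efron_r2": efron,
        "mckelvey_zavoina_r2": mz,
        "count_r2": accuracy,
        "mcfadden_r2": mcfadden,
        "cox_snell_r2": cox_snell,
        "nagelkerke_r2": nagelkerke,
    }
    return MetricsReport(threshold=float(threshold), values=values)


def aggregate_runs(reports: list[MetricsReport]) -> dict[str, dict]:
    """Per-metric sample mean and sd over runs, formatted "m +/- s".

    A metric undefined (NaN) in any run is flagged undefined in the
    aggregate.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    out: dict[str, dict] = {}
    keys = reports[0].values.keys()
    for key in keys:
        vals = np.array([r.values[key] for r in reports], dtype=float)
        if np.any(np.isnan(vals)):
            out[key] = {"mean": _NAN, "sd": _NAN, "formatted": "undefined", "defined": False}
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        out[key] = {
            "mean": mean,
            "sd": sd,
            "formatted": f"{mean:.3f} ± {sd:.3f}",
            "defined": True,
        }
    return out
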