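"""Univariate association analysis for binary risk factors and
rank-based comparison of continuous covariates.

2x2 tables are laid out with the risk category in the first row:

    =============  ======  =========
                   event   no event
    risk category  a       b
    reference      c       d
    =============  ======  =========

Relative risk uses the Katz log interval; independence is tested with the
uncorrected Pearson chi-square when all expected counts are >= 5 and with
Fisher's exact test otherwise.  Continuous covariates are compared with
the Mann-Whitney test and the Hodges-Lehmann shift estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import relative_risk as _scipy_rr

__all__ = [
    "ContingencyTable2x2",
    "RiskEstimate",
    "RankComparison",
    "build_table",
    "relative_risk",
    "chi_square",
    "fisher_exact",
    "expected_counts",
    "factor_report",
    "mann_whitney_hl",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b, c, d) with the risk category in the first row."""

    a: int
    b: int
    c: int
    d: int
    orientation: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")
        if self.total == 0:
            raise ValueError("table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class RiskEstimate:
    rr: float
    ci_low: float
    ci_high: float
    chi2: float | None
    p_value: float
    test_used: str


@dataclass(frozen=True)
class RankComparison:
    u: float
    p_value: float
    median_diff: float
    ci_low: float
    ci_high: float


def build_table(
    cohort: pd.DataFrame,
    factor: str,
    outcome: str = "LEAK",
    risk_category: int = 1,
) -> ContingencyTable2x2:
    """Cross-tabulate one binary factor against the outcome.

    ``risk_category`` names the factor level treated as the risk exposure
    (first row): 1 for comorbidities such as DM, 0 for protective
    interventions such as NoCoil, where *not* applying them carries the
    risk.
    """
    for col in (factor, outcome):
        if col not in cohort.columns:
            raise KeyError(f"column {col!r} not in cohort")
    f = np.asarray(cohort[factor], dtype=int)
    y = np.asarray(cohort[outcome], dtype=int)
    risk = f == risk_category
    return ContingencyTable2x2(
        a=int(np.sum(risk & (y == 1))),
        b=int(np.sum(risk & (y == 0))),
        c=int(np.sum(~risk & (y == 1))),
        d=int(np.sum(~risk & (y == 0))),
        orientation=f"{factor}={'Yes' if risk_category else 'No'}",
    )


def relative_risk(table: ContingencyTable2x2, z: float = 1.96) -> RiskEstimate:
    """Relative risk with the Katz log-scale confidence interval.

    rr = [a/(a+b)] / [c/(c+d)];  CI = exp(ln rr +/- z*s) with
    s = sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + b == 0 or c + d == 0 or c == 0 or a == 0:
        raise ZeroDivisionError("relative risk undefined for this table")
    res = _scipy_rr(a, a + b, c, c + d)
    ci = res.confidence_interval(confidence_level=2 * stats.norm.cdf(z) - 1)
    return RiskEstimate(
        rr=float(res.relative_risk),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        chi2=None,
        p_value=np.nan,
        test_used="",
    )


def expected_counts(table: ContingencyTable2x2) -> np.ndarray:
    obs = table.as_array()
    return stats.contingency.expected_freq(obs)


def chi_square(table: ContingencyTable2x2) -> tuple[float, float]:
    """Uncorrected Pearson chi-square test of independence (df = 1)."""
    obs = table.as_array()
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("degenerate margins: chi-square undefined")
    res = stats.chi2_contingency(obs, correction=False)
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p (hypergeometric mass at or below observed)."""
    return float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])


def factor_report(
    cohort: pd.DataFrame,
    factor: str,
    outcome: str = "LEAK",
    risk_category: int = 1,
    z: float = 1.96,
) -> RiskEstimate:
    """Table-row style summary: RR with CI plus the routed independence test.

    Pearson chi-square when all expected counts are >= 5, Fisher's exact
    test otherwise (only an exact test can report p > 0.999 on sparse
    rows).
    """
    table = build_table(cohort, factor, outcome, risk_category)
    est = relative_risk(table, z=z)
    if expected_counts(table).min() >= 5:
        c2, p = chi_square(table)
        return RiskEstimate(est.rr, est.ci_low, est.ci_high, c2, p, "pearson")
    return RiskEstimate(est.rr, est.ci_low, est.ci_high, None, fisher_exact(table), "fisher")


def _hl_ci(diffs: np.ndarray, m: int, n: int, conf: float) -> tuple[float, float]:
    # conventional rank-order interval on the ordered pairwise differences
    z = stats.norm.ppf(0.5 + conf / 2.0)
    mn = m * n
    c = mn / 2.0 - z * np.sqrt(mn * (m + n + 1) / 12.0)
    k = int(np.floor(c))
    k = max(k, 0)
    if k >= mn:  # pragma: no cover - tiny-sample degenerate
        k = mn - 1
    lo = diffs[k]
    hi = diffs[mn - 1 - k]
    return float(lo), float(hi)


def mann_whitney_hl(x, y, conf: float = 0.95) -> RankComparison:
    """Two-sided Mann-Whitney test with the Hodges-Lehmann shift estimate.

    The p-value uses exact enumeration when both samples have at most 10
    observations and no ties force the normal path, and the tie-corrected
    normal approximation otherwise.  The shift estimate is the median of
    the m*n pairwise differences x_i - y_j with a distribution-based
    confidence interval.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    small = x.size <= 10 and y.size <= 10
    method = "exact" if small and not _has_ties(x, y) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    diffs = np.sort((x[:, None] - y[None, :]).ravel())
    hl = float(np.median(diffs))
    lo, hi = _hl_ci(diffs, x.size, y.size, conf)
    return RankComparison(
        u=float(res.statistic), p_value=float(res.pvalue),
        median_diff=hl, ci_low=lo, ci_high=hi,
    )


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size < pooled.size
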