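"""Synthetic patient-cohort generator.

Draws seeded cohorts of colorectal-surgery patients with four binary
exposures (diabetes, smoking, left-colic-artery preservation, transanal
decompression tube), an optionally coupled fifth exposure (fluorescence
angiography, ICG), a Bernoulli leak outcome driven by a logistic model on
protective-state indicators, and optional per-outcome-group continuous
covariates (CRP and friends).

The default configuration mirrors the marginal structure of a 200-patient
rectal-resection cohort: exposure prevalences 0.275 (NoCoil), 0.50 (ICG),
0.325 (ACSP), 0.18 (DM), 0.17 (Smoking), and a leak prevalence of ~14%
after intercept calibration.

Coding convention
-----------------
The outcome model is expressed on *protective-state* indicators: the
indicator for DM/Smoking is 1 when the comorbidity is absent, and the
indicator for ACSP/NoCoil is 1 when the intervention was applied.  With
negative slopes this makes the risky-vs-protective odds ratio exp(+|beta|),
so e.g. beta_NoCoil = -1.610 means 5.00-fold higher odds of leak without
the tube.  Cohort CSV columns stay in the natural clinical coding
(DM=1 diabetic, NoCoil=1 tube applied, ...).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .logistic import LogisticModel

__all__ = [
    "BINARY_FACTORS",
    "MODEL_FACTORS",
    "CalibrationInfeasibleError",
    "CohortSpec",
    "ContinuousGroupSpec",
    "default_model",
    "default_continuous_specs",
    "protective_indicators",
    "sample_predictors",
    "leak_probability",
    "expected_leak_prevalence",
    "calibrate_intercept",
    "generate_cohort",
]

#: binary exposure columns, clinical coding (1 = factor present / applied)
BINARY_FACTORS = ("DM", "Smoking", "ACSP", "NoCoil", "ICG")
#: covariates entering the outcome model
MODEL_FACTORS = ("DM", "Smoking", "ACSP", "NoCoil")

#: factors whose *absence* is protective (comorbidities)
_RISK_FACTORS = frozenset({"DM", "Smoking"})

DEFAULT_PREVALENCES = {
    "NoCoil": 55 / 200,
    "ICG": 100 / 200,
    "ACSP": 65 / 200,
    "DM": 36 / 200,
    "Smoking": 34 / 200,
}

#: printed final-model slopes on the protective-state scale
DEFAULT_SLOPES = {
    "DM": -1.149,
    "Smoking": -1.429,
    "ACSP": -0.952,
    "NoCoil": -1.610,
}
DEFAULT_INTERCEPT = 1.436


class CalibrationInfeasibleError(ValueError):
    """Requested marginal structure cannot be realised."""


def default_model() -> LogisticModel:
    """Final four-factor leak model with its published slopes."""
    return LogisticModel(
        intercept=DEFAULT_INTERCEPT,
        slopes=dict(DEFAULT_SLOPES),
        coding="protective",
    )


@dataclass(frozen=True)
class ContinuousGroupSpec:
    """Log-normal location/scale for one covariate, per outcome group.

    ``median`` and ``iqr`` (lower, upper quartile) are given on the raw
    measurement scale for the leak and no-leak groups separately.
    """

    median_leak: float
    iqr_leak: tuple[float, float]
    median_no_leak: float
    iqr_no_leak: tuple[float, float]

    def _params(self, leak: bool) -> tuple[float, float]:
        med = self.median_leak if leak else self.median_no_leak
        q1, q3 = self.iqr_leak if leak else self.iqr_no_leak
        mu = np.log(med)
        # ln q3 - ln q1 = 2 * 0.6745 * sigma for a log-normal
        sigma = np.log(q3 / q1) / (2 * 0.674489750196082)
        return mu, sigma

    def sample(self, leak: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.empty(leak.shape[0])
        for flag in (True, False):
            mask = leak.astype(bool) == flag
            if mask.any():
                mu, sigma = self._params(flag)
                out[mask] = rng.lognormal(mu, sigma, mask.sum())
        return out


def default_continuous_specs() -> dict[str, ContinuousGroupSpec]:
    """Median/IQR-matched log-normal specs for the quantitative covariates."""
    return {
        "CRP": ContinuousGroupSpec(108, (78, 131), 62, (34, 94)),
        "BMI": ContinuousGroupSpec(28, (24, 31), 26, (24, 29)),
        "LN": ContinuousGroupSpec(13, (6, 16), 13, (8, 17)),
        "Age": ContinuousGroupSpec(65, (60, 67), 65, (58, 71)),
        "HB": ContinuousGroupSpec(115, (103, 121), 116, (107, 123)),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one synthetic cohort."""

    n: int = 200
    seed: int = 0
    exposure_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    icg_nocoil_odds_ratio: float = 4.0
    coefficients: LogisticModel = field(default_factory=default_model)
    target_prevalence: float | None = 0.14
    continuous_specs: dict[str, ContinuousGroupSpec] | None = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.icg_nocoil_odds_ratio <= 0:
            raise ValueError("icg_nocoil_odds_ratio must be positive")
        for name, p in self.exposure_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {name} outside [0, 1]")
        if self.target_prevalence is not None and not (
            0.0 < self.target_prevalence < 1.0
        ):
            raise ValueError("target_prevalence must lie in (0, 1)")


def _icg_conditionals(p_icg: float, p_nocoil: float, odds_ratio: float) -> tuple[float, float]:
    """P(ICG=1 | NoCoil=0) and P(ICG=1 | NoCoil=1) matching both margins.

    Solves the 2x2 cell probabilities from the two margins and the odds
    ratio (Plackett's quadratic), then conditions on NoCoil.
    """
    lo, hi = max(0.0, p_icg + p_nocoil - 1.0), min(p_icg, p_nocoil)
    if abs(odds_ratio - 1.0) < 1e-12:
        p11 = p_icg * p_nocoil
    else:
        psi = odds_ratio
        s = 1.0 + (p_icg + p_nocoil) * (psi - 1.0)
        disc = s * s - 4.0 * psi * (psi - 1.0) * p_icg * p_nocoil
        if disc < 0:
            raise CalibrationInfeasibleError(
                "no joint distribution matches the margins and odds ratio"
            )
        p11 = (s - np.sqrt(disc)) / (2.0 * (psi - 1.0))
    if not (lo - 1e-12 <= p11 <= hi + 1e-12):
        raise CalibrationInfeasibleError(
            "no joint distribution matches the margins and odds ratio"
        )
    p11 = float(np.clip(p11, lo, hi))
    p_given_yes = p11 / p_nocoil if p_nocoil > 0 else 0.0
    p_given_no = (p_icg - p11) / (1.0 - p_nocoil) if p_nocoil < 1 else 0.0
    return float(np.clip(p_given_no, 0, 1)), float(np.clip(p_given_yes, 0, 1))


def sample_predictors(spec: CohortSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample the binary exposure matrix.

    DM, Smoking, ACSP and NoCoil are independent Bernoulli draws at their
    prevalences; ICG is drawn conditionally on NoCoil so the population
    ICG-by-NoCoil odds ratio equals ``spec.icg_nocoil_odds_ratio`` while
    preserving the ICG marginal.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    prev = spec.exposure_prevalences
    cols = {}
    for name in ("DM", "Smoking", "ACSP", "NoCoil"):
        cols[name] = (rng.random(spec.n) < prev[name]).astype(np.int64)
    p_no, p_yes = _icg_conditionals(
        prev["ICG"], prev["NoCoil"], spec.icg_nocoil_odds_ratio
    )
    p_cond = np.where(cols["NoCoil"] == 1, p_yes, p_no)
    cols["ICG"] = (rng.random(spec.n) < p_cond).astype(np.int64)
    return pd.DataFrame(cols, columns=list(BINARY_FACTORS))


def protective_indicators(exposures: pd.DataFrame, factors=MODEL_FACTORS) -> np.ndarray:
    """Map clinically coded exposures to protective-state indicators.

    Comorbidities flip (1 = absent); interventions pass through (1 = applied).
    """
    cols = []
    for name in factors:
        col = np.asarray(exposures[name], dtype=float)
        cols.append(1.0 - col if name in _RISK_FACTORS else col)
    return np.column_stack(cols) if cols else np.empty((len(exposures), 0))


def leak_probability(exposures: pd.DataFrame, model: LogisticModel) -> np.ndarray:
    """Per-patient leak probability under the protective-coding model."""
    factors = tuple(model.slopes)
    missing = [f for f in factors if f not in exposures.columns]
    if missing:
        raise ValueError(f"exposure matrix lacks model covariates: {missing}")
    x = protective_indicators(exposures, factors)
    beta = np.array([model.slopes[f] for f in factors])
    return expit(model.intercept + x @ beta)


def _cell_table(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Exact joint over the 2^4 model-exposure cells (independent margins)."""
    prev = spec.exposure_prevalences
    probs, rows = [], []
    for bits in itertools.product((0, 1), repeat=len(MODEL_FACTORS)):
        p = 1.0
        for name, b in zip(MODEL_FACTORS, bits):
            p *= prev[name] if b else 1.0 - prev[name]
        probs.append(p)
        rows.append(bits)
    return np.array(rows, dtype=float), np.array(probs)


def expected_leak_prevalence(spec: CohortSpec, intercept: float | None = None) -> float:
    """Exact expected marginal leak probability by cell enumeration."""
    model = spec.coefficients
    if intercept is not None:
        model = replace(model, intercept=intercept)
    rows, probs = _cell_table(spec)
    cells = pd.DataFrame(rows, columns=list(MODEL_FACTORS))
    return float(probs @ leak_probability(cells, model))


def calibrate_intercept(spec: CohortSpec, tol: float = 1e-10) -> float:
    """Intercept at which the enumerated marginal leak probability hits
    ``spec.target_prevalence`` (to well within 1e-6).

    The expectation is monotone increasing in the intercept, so a bracketed
    root solve always succeeds when the target is attainable (any target in
    (0, 1) is, in the limit of an infinite intercept of either sign).
    """
    if spec.target_prevalence is None:
        raise ValueError("spec.target_prevalence is not set")
    target = spec.target_prevalence

    def gap(b0: float) -> float:
        return expected_leak_prevalence(spec, intercept=b0) - target

    lo, hi = -50.0, 50.0
    if gap(lo) > 0 or gap(hi) < 0:  # pragma: no cover - requires target ~0 or ~1
        raise CalibrationInfeasibleError("target prevalence outside attainable range")
    return float(brentq(gap, lo, hi, xtol=tol))


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a full cohort: exposures, Bernoulli LEAK outcome, optional
    continuous covariates.  Identical spec (including seed) gives an
    identical frame.
    """
    rng = np.random.default_rng(spec.seed)
    exposures = sample_predictors(spec, rng)
    model = spec.coefficients
    if spec.target_prevalence is not None:
        model = replace(model, intercept=calibrate_intercept(spec))
    p = leak_probability(exposures, model) if spec.n else np.empty(0)
    leak = (rng.random(spec.n) < p).astype(np.int64)
    cohort = exposures.assign(LEAK=leak)
    if spec.continuous_specs:
        for name, cs in spec.continuous_specs.items():
            cohort[name] = cs.sample(leak, rng)
    cohort.attrs["spec"] = spec
    return cohort
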