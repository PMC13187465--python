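"""Synthetic cohort generator: marginal structure, outcome model,
intercept calibration and determinism."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from qalbench.cohort import (
    BINARY_FACTORS,
    MODEL_FACTORS,
    CohortSpec,
    calibrate_intercept,
    default_continuous_specs,
    default_model,
    expected_leak_prevalence,
    generate_cohort,
    leak_probability,
    sample_predictors,
)
from qalbench.logistic import LogisticModel


class TestSamplePredictors:
    def test_marginal_prevalences_converge(self, large_cohort):
        prev = large_cohort[list(BINARY_FACTORS)].mean()
        assert prev["NoCoil"] == pytest.approx(0.275, abs=0.005)
        assert prev["ICG"] == pytest.approx(0.50, abs=0.005)
        assert prev["ACSP"] == pytest.approx(0.325, abs=0.005)
        assert prev["DM"] == pytest.approx(0.18, abs=0.005)
        assert prev["Smoking"] == pytest.approx(0.17, abs=0.005)

    def test_empty_cohort(self):
        X = sample_predictors(CohortSpec(n=0, seed=0))
        assert len(X) == 0 and list(X.columns) == list(BINARY_FACTORS)

    def test_icg_nocoil_odds_ratio_matches_analytic_cells(self):
        # oracle: solve the 2x2 cell probabilities from margins + OR, then
        # compare the empirical table of a large sample
        target_or = 4.0
        spec = CohortSpec(n=200_000, seed=7, icg_nocoil_odds_ratio=target_or)
        X = sample_predictors(spec)
        t = pd.crosstab(X["ICG"], X["NoCoil"])
        sample_or = (t.loc[1, 1] * t.loc[0, 0]) / (t.loc[1, 0] * t.loc[0, 1])
        assert sample_or == pytest.approx(target_or, abs=0.2)
        # margins preserved under the coupling
        assert X["ICG"].mean() == pytest.approx(0.5, abs=0.005)

    def test_extreme_coupling_still_preserves_margins(self):
        # the margin/odds-ratio solve stays on the feasible cell simplex
        # even for a near-degenerate association
        spec = CohortSpec(n=100_000, seed=13, icg_nocoil_odds_ratio=100.0)
        X = sample_predictors(spec)
        assert X["ICG"].mean() == pytest.approx(0.5, abs=0.01)
        assert X["NoCoil"].mean() == pytest.approx(0.275, abs=0.01)
        # nearly every tube patient also gets angiography at this coupling
        assert X.loc[X.NoCoil == 1, "ICG"].mean() > 0.9


class TestLeakProbability:
    def test_all_risk_patient(self):
        # every protective indicator is 0, so the logit is the intercept
        row = pd.DataFrame({"DM": [1], "Smoking": [1], "ACSP": [0], "NoCoil": [0]})
        assert leak_probability(row, default_model())[0] == pytest.approx(0.8078, abs=5e-5)

    def test_all_protective_patient(self):
        row = pd.DataFrame({"DM": [0], "Smoking": [0], "ACSP": [1], "NoCoil": [1]})
        assert leak_probability(row, default_model())[0] == pytest.approx(0.0240, abs=5e-5)

    def test_zero_coefficients_give_half(self):
        model = LogisticModel(0.0, {f: 0.0 for f in MODEL_FACTORS})
        rows = pd.DataFrame(
            {f: np.random.default_rng(0).integers(0, 2, 20) for f in MODEL_FACTORS}
        )
        assert np.allclose(leak_probability(rows, model), 0.5)

    def test_missing_covariate_raises(self):
        row = pd.DataFrame({"DM": [1]})
        with pytest.raises(ValueError, match="lacks model covariates"):
            leak_probability(row, default_model())


class TestCalibrateIntercept:
    def test_fixed_point(self):
        spec = CohortSpec(n=10, seed=0, target_prevalence=None)
        implied = expected_leak_prevalence(spec)
        spec2 = CohortSpec(n=10, seed=0, target_prevalence=implied)
        assert calibrate_intercept(spec2) == pytest.approx(default_model().intercept, abs=1e-6)

    def test_monotone_in_target_against_bisection_oracle(self):
        def bisect(target):
            lo, hi = -30.0, 30.0
            spec = CohortSpec(n=10, seed=0, target_prevalence=target)
            for _ in range(200):
                mid = (lo + hi) / 2
                if expected_leak_prevalence(spec, mid) < target:
                    lo = mid
                else:
                    hi = mid
            return (lo + hi) / 2

        targets = [0.05, 0.14, 0.30, 0.60]
        sols = []
        for t in targets:
            spec = CohortSpec(n=10, seed=0, target_prevalence=t)
            b0 = calibrate_intercept(spec)
            assert b0 == pytest.approx(bisect(t), abs=1e-6)
            sols.append(b0)
        assert np.all(np.diff(sols) > 0)

    def test_default_target_hits_14_percent_by_enumeration(self):
        spec = CohortSpec(n=10, seed=0)
        b0 = calibrate_intercept(spec)
        assert expected_leak_prevalence(spec, b0) == pytest.approx(0.14, abs=1e-6)
        # the printed slopes with independent exposures overshoot 14%,
        # so the calibrated intercept must be below the printed one
        assert b0 < default_model().intercept


class TestGenerateCohort:
    def test_calibrated_leak_prevalence(self, large_cohort):
        assert large_cohort["LEAK"].mean() == pytest.approx(0.14, abs=0.005)

    def test_forced_zero_probability_means_no_leaks(self):
        model = LogisticModel(-60.0, {f: 0.0 for f in MODEL_FACTORS})
        spec = CohortSpec(n=2000, seed=3, coefficients=model, target_prevalence=None)
        assert generate_cohort(spec)["LEAK"].sum() == 0

    def test_same_seed_gives_byte_identical_csv(self):
        spec = CohortSpec(n=500, seed=11, continuous_specs=default_continuous_specs())
        bufs = []
        for _ in range(2):
            buf = io.StringIO()
            generate_cohort(spec).to_csv(buf, index=False)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_continuous_covariates_track_group_medians(self):
        spec = CohortSpec(n=100_000, seed=5, continuous_specs=default_continuous_specs())
        cohort = generate_cohort(spec)
        crp_leak = cohort.loc[cohort.LEAK == 1, "CRP"].median()
        crp_ok = cohort.loc[cohort.LEAK == 0, "CRP"].median()
        assert crp_leak == pytest.approx(108, rel=0.05)
        assert crp_ok == pytest.approx(62, rel=0.05)

    def test_enumeration_matches_monte_carlo(self, large_cohort):
        spec = large_cohort.attrs["spec"]
        b0 = calibrate_intercept(spec)
        exact = expected_leak_prevalence(spec, b0)
        n = len(large_cohort)
        se = np.sqrt(exact * (1 - exact) / n)
        assert abs(large_cohort["LEAK"].mean() - exact) < 3 * se

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n=-1)
        with pytest.raises(ValueError):
            CohortSpec(icg_nocoil_odds_ratio=0.0)
        with pytest.raises(ValueError):
            CohortSpec(target_prevalence=1.5)


def test_generator_model_roundtrip_recovers_slopes(large_cohort):
    """Fitting the logistic model on generated data recovers each
    calibrated-generator coefficient (identifiability of the design)."""
    from qalbench.cohort import protective_indicators
    from qalbench.logistic import fit_logistic

    sub = large_cohort.iloc[:50_000]
    X = protective_indicators(sub)
    fit = fit_logistic(pd.DataFrame(X, columns=list(MODEL_FACTORS)), sub["LEAK"])
    for name, beta in default_model().slopes.items():
        assert fit.model.slopes[name] == pytest.approx(beta, abs=0.05)
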