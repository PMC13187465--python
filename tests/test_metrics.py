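"""Discrimination, calibration, fixed-sensitivity thresholds and
aggregation, with brute-force and sklearn oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import average_precision_score, roc_auc_score

from qalbench.metrics import (
    ThresholdPolicy,
    aggregate_runs,
    average_precision,
    calibration_metrics,
    classification_report,
    roc_auc,
    threshold_at_sensitivity,
)


def brute_force_auc(y, s):
    y, s = np.asarray(y), np.asarray(s)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_and_reversed_ranking(self):
        y = [0, 0, 1, 1]
        assert roc_auc(y, [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert roc_auc(y, [0.9, 0.8, 0.2, 0.1]) == 0.0

    def test_tie_counts_half(self):
        # four positive-negative pairs: one tied (0.5), one loss (0.8 vs
        # 0.9) and two wins -> 2.5 / 4
        assert roc_auc([1, 0, 1, 0], [0.9, 0.9, 0.8, 0.1]) == pytest.approx(0.625)

    @given(
        st.lists(st.integers(0, 1), min_size=2, max_size=12),
        st.data(),
    )
    @settings(max_examples=120, deadline=None)
    def test_matches_exhaustive_pair_counting(self, labels, data):
        if len(set(labels)) < 2:
            labels = labels[:-1] + [1 - labels[-1]]
        scores = data.draw(
            st.lists(
                st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]),
                min_size=len(labels), max_size=len(labels),
            )
        )
        assert roc_auc(labels, scores) == pytest.approx(
            brute_force_auc(labels, scores), abs=1e-12
        )

    def test_matches_sklearn(self, rng):
        y = rng.integers(0, 2, 100)
        y[0], y[1] = 0, 1
        s = rng.random(100).round(1)  # force ties
        assert roc_auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.2, 0.3])


class TestAveragePrecision:
    def test_matches_sklearn(self, rng):
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        s = rng.random(200)
        assert average_precision(y, s) == pytest.approx(
            average_precision_score(y, s), abs=1e-10
        )

    def test_at_least_prevalence_for_random_scores(self, rng):
        y = rng.integers(0, 2, 500)
        assert average_precision(y, np.full(500, 0.3)) == pytest.approx(y.mean())


class TestCalibration:
    def test_perfect_predictions(self):
        brier, ll = calibration_metrics([1, 0], [1.0, 0.0])
        assert brier == 0.0 and ll == pytest.approx(0.0, abs=1e-10)

    def test_coin_flip(self):
        brier, ll = calibration_metrics([1, 0], [0.5, 0.5])
        assert brier == pytest.approx(0.25)
        assert ll == pytest.approx(np.log(2), abs=1e-12)

    def test_worked_brier(self):
        brier, _ = calibration_metrics([1, 0], [0.8, 0.3])
        assert brier == pytest.approx(0.065)

    def test_brier_murphy_decomposition_on_binned_data(self):
        # probabilities constant within bins: brier = calibration + refinement
        y = np.array([1, 0, 0, 1, 1, 1, 0, 0, 1, 0])
        p = np.array([0.2, 0.2, 0.2, 0.2, 0.8, 0.8, 0.8, 0.5, 0.5, 0.5])
        brier, _ = calibration_metrics(y, p)
        total = 0.0
        for level in np.unique(p):
            mask = p == level
            ybar = y[mask].mean()
            w = mask.mean()
            total += w * ((level - ybar) ** 2 + ybar * (1 - ybar))
        assert brier == pytest.approx(total, abs=1e-9)


class TestThresholdAtSensitivity:
    def test_perfect_scores(self):
        y = [1, 1, 0, 0]
        t = threshold_at_sensitivity(y, [1.0, 1.0, 0.0, 0.0])
        report = classification_report(y, [1.0, 1.0, 0.0, 0.0], t)
        assert report["recall"] == 1.0
        assert report["f1"] == 1.0

    def test_worked_20_point_set_admits_5_of_6_positives(self, rng):
        scores = np.round(np.linspace(0.05, 1.0, 20), 2)
        y = np.zeros(20)
        y[[19, 18, 16, 13, 10, 4]] = 1  # 6 positives, one deep in the noise
        t = threshold_at_sensitivity(y, scores, ThresholdPolicy(0.83, beta=2))
        rep = classification_report(y, scores, t)
        assert rep["recall"] >= 5 / 6 - 1e-12

    def test_all_scores_equal_degenerate(self):
        y = [1, 0, 0, 1]
        t = threshold_at_sensitivity(y, [0.4] * 4)
        rep = classification_report(y, [0.4] * 4, t)
        assert rep["recall"] == 1.0
        assert rep["specificity"] == 0.0

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            threshold_at_sensitivity([0, 0], [0.1, 0.2])


class TestClassificationReport:
    def test_confusion_arithmetic(self):
        # TP=5 FN=1 FP=18 TN=34
        y = np.r_[np.ones(6), np.zeros(52)]
        p = np.r_[np.full(5, 0.9), [0.1], np.full(18, 0.9), np.full(34, 0.1)]
        rep = classification_report(y, p, 0.5)
        assert rep["recall"] == pytest.approx(0.833, abs=5e-4)
        assert rep["specificity"] == pytest.approx(0.654, abs=5e-4)
        assert rep["ppv"] == pytest.approx(0.217, abs=5e-4)
        assert rep["npv"] == pytest.approx(0.971, abs=5e-4)
        assert rep["accuracy"] == pytest.approx(0.672, abs=5e-4)

    def test_probabilities_equal_labels(self):
        y = [1, 0, 1, 0]
        rep = classification_report(y, [1.0, 0.0, 1.0, 0.0], 0.5)
        for key in ("accuracy", "recall", "specificity", "ppv", "npv", "efron_r2"):
            assert rep[key] == pytest.approx(1.0)

    def test_constant_base_rate_prediction_zeroes_efron(self):
        y = np.array([1, 0, 0, 0])
        rep = classification_report(y, np.full(4, y.mean()), 0.5)
        assert rep["efron_r2"] == pytest.approx(0.0, abs=1e-12)

    def test_count_r2_equals_accuracy(self, rng):
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        p = rng.random(60)
        for t in (0.2, 0.5, 0.8):
            rep = classification_report(y, p, t)
            assert rep["count_r2"] == rep["accuracy"]

    def test_pseudo_r2_orderings(self, rng):
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        p = np.clip(0.3 + 0.4 * y + rng.normal(0, 0.1, 200), 0.01, 0.99)
        rep = classification_report(y, p, 0.5)
        for key in ("mcfadden_r2", "cox_snell_r2", "nagelkerke_r2"):
            assert 0.0 <= rep[key] <= 1.0
        assert rep["nagelkerke_r2"] >= rep["cox_snell_r2"]

    def test_degenerate_denominator_reported_as_nan(self):
        y = [1, 1, 0, 0]
        rep = classification_report(y, [0.1, 0.2, 0.1, 0.3], 0.9)
        assert np.isnan(rep["ppv"])  # nothing predicted positive


class TestAggregateRuns:
    def _rep(self, auc):
        y, p = [1, 0, 1, 0], [0.8, 0.3, 0.7, 0.4]
        rep = classification_report(y, p, 0.5)
        rep.values["auc"] = auc
        return rep

    def test_single_report_sd_zero(self):
        agg = aggregate_runs([self._rep(0.8)])
        assert agg["auc"]["sd"] == 0.0

    def test_mean_and_sd(self):
        agg = aggregate_runs([self._rep(a) for a in (0.78, 0.80, 0.82)])
        assert agg["auc"]["mean"] == pytest.approx(0.80)
        assert agg["auc"]["sd"] == pytest.approx(0.02)
        assert agg["auc"]["formatted"] == "0.800 ± 0.020"

    def test_undefined_metric_propagates(self):
        r1, r2 = self._rep(0.8), self._rep(float("nan"))
        agg = aggregate_runs([r1, r2])
        assert not agg["auc"]["defined"]
        assert agg["auc"]["formatted"] == "undefined"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_runs([])
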