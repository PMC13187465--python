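"""Contingency-table statistics against the published-table counts and
independent combinatorial oracles."""

import itertools

import numpy as np
import pytest
from scipy.stats import hypergeom

from qalbench.risk_stats import (
    ContingencyTable2x2,
    build_table,
    chi_square,
    expected_counts,
    factor_report,
    fisher_exact,
    mann_whitney_hl,
    relative_risk,
)

from conftest import expand_table


# (a, b, c, d) -> published RR and CI for the four significant factors
PRINTED_ROWS = {
    "NoCoil": ((25, 120, 3, 52), 3.16, (0.99, 10.05)),
    "DM": ((9, 27, 19, 145), 2.16, (1.06, 4.37)),
    "Smoking": ((9, 25, 19, 147), 2.31, (1.15, 4.67)),
    "ICG": ((19, 81, 9, 91), 2.11, (1.00, 4.44)),
}


class TestBuildTable:
    def test_reconstructs_the_published_layout(self):
        cohort = expand_table(25, 120, 3, 52).rename(
            columns={"x": "NoCoil", "y": "LEAK"}
        )
        # risk category for an intervention is *not* applying it
        cohort["NoCoil"] = 1 - cohort["NoCoil"]
        t = build_table(cohort, "NoCoil", risk_category=0)
        assert (t.a, t.b, t.c, t.d) == (25, 120, 3, 52)
        assert t.orientation == "NoCoil=No"

    def test_single_patient(self):
        cohort = expand_table(1, 0, 0, 0).rename(columns={"x": "DM", "y": "LEAK"})
        t = build_table(cohort, "DM")
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 0)

    def test_empty_cohort_rejected(self):
        cohort = expand_table(0, 0, 0, 0).rename(columns={"x": "DM", "y": "LEAK"})
        with pytest.raises(ValueError):
            build_table(cohort, "DM")

    def test_unknown_column(self, clinic_cohort):
        with pytest.raises(KeyError):
            build_table(clinic_cohort, "CoffeeIntake")


class TestRelativeRisk:
    @pytest.mark.parametrize("factor", sorted(PRINTED_ROWS))
    def test_printed_rows(self, factor):
        counts, rr, _ = PRINTED_ROWS[factor]
        est = relative_risk(ContingencyTable2x2(*counts))
        assert round(est.rr, 2) == rr

    def test_nocoil_confidence_interval(self):
        counts, _, ci = PRINTED_ROWS["NoCoil"]
        est = relative_risk(ContingencyTable2x2(*counts))
        assert (round(est.ci_low, 2), round(est.ci_high, 2)) == ci

    def test_no_association_gives_unity(self):
        est = relative_risk(ContingencyTable2x2(10, 30, 5, 15))
        assert est.rr == pytest.approx(1.0)

    def test_scale_equivariance(self):
        t1 = ContingencyTable2x2(9, 27, 19, 145)
        t10 = ContingencyTable2x2(90, 270, 190, 1450)
        e1, e10 = relative_risk(t1), relative_risk(t10)
        assert e10.rr == pytest.approx(e1.rr)
        assert (e10.ci_high - e10.ci_low) < (e1.ci_high - e1.ci_low)

    def test_zero_cell_rejected(self):
        with pytest.raises(ZeroDivisionError):
            relative_risk(ContingencyTable2x2(5, 5, 0, 10))


class TestChiSquare:
    def test_printed_p_values(self):
        assert round(chi_square(ContingencyTable2x2(25, 120, 3, 52))[1], 3) == 0.032
        assert round(chi_square(ContingencyTable2x2(19, 81, 9, 91))[1], 3) == 0.042

    def test_null_table(self):
        stat, p = chi_square(ContingencyTable2x2(10, 30, 5, 15))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_equals_squared_two_proportion_z(self):
        t = ContingencyTable2x2(25, 120, 3, 52)
        p1, p2 = t.a / (t.a + t.b), t.c / (t.c + t.d)
        n1, n2 = t.a + t.b, t.c + t.d
        pool = (t.a + t.c) / t.total
        z = (p1 - p2) / np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
        assert chi_square(t)[0] == pytest.approx(z ** 2, rel=1e-10)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square(ContingencyTable2x2(0, 10, 0, 20))

    def test_type_one_error_on_nocoil_margins(self, rng):
        # 10k null tables with the NoCoil design: row sizes 145/55,
        # common event rate 28/200
        n1, n2, p0, reps = 145, 55, 28 / 200, 10_000
        a = rng.binomial(n1, p0, reps).astype(float)
        c = rng.binomial(n2, p0, reps).astype(float)
        b, d = n1 - a, n2 - c
        n = float(n1 + n2)
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        from scipy.stats import chi2

        rej = np.nanmean(chi2.sf(stat, 1) < 0.05)
        assert abs(rej - 0.05) < 0.01


class TestFisherExact:
    def test_sparse_published_row_exceeds_0_999(self):
        assert fisher_exact(ContingencyTable2x2(27, 164, 1, 8)) > 0.999

    def test_fully_separated_small_table(self):
        # exhaustive: only the two extreme tables have mass <= observed
        assert fisher_exact(ContingencyTable2x2(5, 0, 0, 5)) == pytest.approx(
            2 / 252, rel=1e-9
        )

    def test_zero_row_margin_gives_one(self):
        assert fisher_exact(ContingencyTable2x2(0, 0, 5, 9)) == pytest.approx(1.0)

    @pytest.mark.parametrize("margins", [(6, 9, 7), (12, 8, 10), (20, 15, 5)])
    def test_agrees_with_hypergeometric_enumeration(self, margins):
        r1, r2, col1 = margins
        n = r1 + r2
        for a in range(max(0, col1 - r2), min(r1, col1) + 1):
            t = ContingencyTable2x2(a, r1 - a, col1 - a, r2 - (col1 - a))
            p_obs = hypergeom.pmf(a, n, r1, col1)
            total = sum(
                hypergeom.pmf(k, n, r1, col1)
                for k in range(max(0, col1 - r2), min(r1, col1) + 1)
                if hypergeom.pmf(k, n, r1, col1) <= p_obs * (1 + 1e-9)
            )
            assert fisher_exact(t) == pytest.approx(min(total, 1.0), rel=1e-7)


class TestRouting:
    def test_large_cells_use_pearson(self):
        cohort = expand_table(9, 27, 19, 145).rename(columns={"x": "DM", "y": "LEAK"})
        rep = factor_report(cohort, "DM", risk_category=1)
        assert rep.test_used == "pearson"
        assert round(rep.p_value, 3) == 0.036

    def test_sparse_cells_use_fisher(self):
        cohort = expand_table(2, 5, 26, 167).rename(columns={"x": "CORT", "y": "LEAK"})
        assert expected_counts(build_table(cohort, "CORT")).min() < 5
        rep = factor_report(cohort, "CORT")
        assert rep.test_used == "fisher"


class TestMannWhitneyHL:
    def test_identical_samples(self):
        rc = mann_whitney_hl([1, 2, 2, 3], [1, 2, 2, 3])
        assert rc.median_diff == pytest.approx(0.0)
        assert rc.p_value == pytest.approx(1.0, abs=0.05)

    def test_separated_samples_exact(self):
        # all 9 pairwise differences are negative; exact U distribution
        rc = mann_whitney_hl([1, 2, 3], [4, 5, 6])
        assert rc.u == 0
        assert rc.median_diff == pytest.approx(-3.0)
        assert rc.p_value == pytest.approx(0.1, abs=1e-9)  # 2 * 1/C(6,3)

    def test_shift_alternative_recovery(self, rng):
        # pure location shift of 46 between groups of 200
        x = rng.normal(100.0, 10.0, 200) + 46.0
        y = rng.normal(100.0, 10.0, 200)
        rc = mann_whitney_hl(x, y)
        assert rc.median_diff == pytest.approx(46.0, abs=3.0)
        assert rc.ci_low < rc.median_diff < rc.ci_high
        assert rc.p_value < 0.001

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_hl([], [1.0])
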