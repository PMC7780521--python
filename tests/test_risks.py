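"""Relative risks: Katz CI arithmetic, cross-checks, screen and demographics."""

import numpy as np
import pytest

from conftest import build_cohort
from vaxtiming.classify import classify_cohort
from vaxtiming.risks import (
    covariate_screen,
    demographics_table,
    outcome_frame,
    relative_risk,
)


class TestRelativeRisk:
    def test_direct_arithmetic(self):
        est = relative_risk(10, 90, 20, 80)
        assert est.rr == pytest.approx(0.5)

    @pytest.mark.parametrize("k,m", [(5, 5), (20, 80), (1, 99)])
    def test_symmetry_gives_unity(self, k, m):
        est = relative_risk(k, m, k, m)
        assert est.rr == pytest.approx(1.0)
        assert est.ci_low < 1.0 < est.ci_high

    def test_katz_interval_hand_computation(self):
        """(50,50,25,75): RR=2, CI = exp(ln2 +/- 1.96*0.2) ~ (1.35, 2.96)."""
        est = relative_risk(50, 50, 25, 75)
        assert est.rr == pytest.approx(2.0)
        se = np.sqrt(1 / 50 - 1 / 100 + 1 / 25 - 1 / 100)
        assert est.ci_low == pytest.approx(np.exp(np.log(2) - 1.959963984540054 * se))
        assert est.ci_high == pytest.approx(np.exp(np.log(2) + 1.959963984540054 * se))
        assert 1.35 < est.ci_low < 1.36
        assert 2.95 < est.ci_high < 2.97

    def test_agrees_with_statsmodels(self):
        """Independent cross-check against statsmodels' 2x2 table methods."""
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        table = sm.Table2x2(np.array([[30, 70], [15, 85]]))
        est = relative_risk(30, 70, 15, 85)
        assert est.rr == pytest.approx(table.riskratio)
        lo, hi = table.riskratio_confint(0.05)
        assert est.ci_low == pytest.approx(lo, rel=1e-6)
        assert est.ci_high == pytest.approx(hi, rel=1e-6)

    def test_risk_conservation_identity(self):
        est = relative_risk(12, 34, 9, 45)
        assert 12 / 46 == pytest.approx(est.rr * 9 / 54)

    def test_zero_cell_haldane_flagged(self):
        est = relative_risk(0, 50, 10, 40)
        assert est.continuity_corrected and est.defined
        assert est.rr == pytest.approx((0.5 / 51) / (10.5 / 51))

    def test_zero_margin_undefined(self):
        est = relative_risk(0, 0, 10, 40)
        assert not est.defined and np.isnan(est.rr)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            relative_risk(-1, 5, 5, 5)

    def test_katz_agrees_with_bootstrap(self):
        """Katz CI close to a nonparametric bootstrap CI on moderate counts."""
        a, b, c, d = 60, 140, 40, 160
        est = relative_risk(a, b, c, d)
        rng = np.random.default_rng(0)
        exposed = np.repeat([1, 0], [a, b])
        unexposed = np.repeat([1, 0], [c, d])
        boots = []
        for _ in range(4000):
            e = rng.choice(exposed, size=a + b, replace=True).mean()
            u = rng.choice(unexposed, size=c + d, replace=True).mean()
            if u > 0:
                boots.append(e / u)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        assert est.ci_low == pytest.approx(lo, abs=0.12)
        assert est.ci_high == pytest.approx(hi, abs=0.25)


@pytest.fixture
def covariate_cohort():
    infants = {}
    for i in range(40):
        vaccinated = i % 4 != 0  # 75% get all three doses
        infants[f"I{i:02d}"] = {
            "visit_ages": [42, 70, 98],
            "dose_ages": [43, 72, 100] if vaccinated else [],
            "female": int(i % 2 == 0),
            "maternal_age": 20 + (i % 15),
        }
    return build_cohort(infants)


class TestScreen:
    def test_grid_shape_and_baseline(self, schedule, covariate_cohort):
        cls = classify_cohort(schedule, covariate_cohort)
        out = outcome_frame(cls)
        assert out["all_doses"].mean() == pytest.approx(0.75)
        screen = covariate_screen(covariate_cohort, cls, covariates=["female", "maternal_age"])
        assert len(screen) == 6  # 2 covariates x 3 outcomes
        assert set(screen["outcome"]) == {"unvaccinated", "at_least_1_dose", "all_doses"}
        assert (screen.loc[screen["covariate"] == "maternal_age", "coding"] == "above-median").all()

    def test_constant_covariate_flagged_undefined(self, schedule, covariate_cohort):
        cohort = covariate_cohort
        cohort.roster["always_one"] = 1
        cls = classify_cohort(schedule, cohort)
        screen = covariate_screen(cohort, cls, covariates=["always_one"])
        assert (~screen["defined"]).all()

    def test_independent_covariate_ci_coverage(self, schedule):
        """CIs for a covariate independent of the outcome cover RR=1 at ~95%."""
        rng = np.random.default_rng(123)
        covered = total = 0
        for _ in range(300):
            n = 400
            x = rng.random(n) < 0.5
            y = rng.random(n) < 0.3  # outcome independent of x
            a, b = int((y & x).sum()), int((~y & x).sum())
            c, d = int((y & ~x).sum()), int((~y & ~x).sum())
            est = relative_risk(a, b, c, d)
            if est.defined and np.isfinite(est.rr):
                total += 1
                covered += est.ci_low <= 1.0 <= est.ci_high
        assert covered / total == pytest.approx(0.95, abs=0.035)


class TestDemographics:
    def test_strata_counts_nested(self, schedule):
        cohort = build_cohort(
            {
                "A": {"visit_ages": [21, 42, 56, 70, 84, 98], "female": 1, "maternal_age": 24},
                "B": {"visit_ages": [42, 70], "female": 0, "maternal_age": 30},
                "C": {"visit_ages": [], "female": 1, "maternal_age": 21},
            }
        )
        table = demographics_table(cohort, n_scheduled_visits=6).set_index("covariate")
        counts = table.loc["n_infants"]
        assert (counts["enrolled"], counts["attending"], counts["completed"]) == (3, 2, 1)

    def test_no_dropout_strata_identical(self, schedule):
        cohort = build_cohort(
            {f"I{i}": {"visit_ages": [21, 42, 56, 70, 84, 98], "female": i % 2} for i in range(8)}
        )
        table = demographics_table(cohort, n_scheduled_visits=6)
        assert (table["enrolled"] == table["attending"]).all()
        assert (table["attending"] == table["completed"]).all()

    def test_median_iqr_hand_fixture(self, schedule):
        ages = [19, 22, 25, 31, 38]
        cohort = build_cohort(
            {f"I{i}": {"visit_ages": [42], "maternal_age": a} for i, a in enumerate(ages)}
        )
        row = demographics_table(cohort).set_index("covariate").loc["maternal_age"]
        assert row["enrolled"] == 25.0
        assert row["enrolled_iqr_low"] == 22.0
        assert row["enrolled_iqr_high"] == 31.0
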