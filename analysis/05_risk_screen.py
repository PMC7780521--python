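#!/usr/bin/env python
"""Relative-risk screen of demographic covariates and demographics table.

Screens every roster covariate against the three end-of-study outcomes
(unvaccinated, at least one dose, full series) with unadjusted relative
risks and Katz 95% CIs, and summarises demographics by attendance
stratum.  In the synthetic cohort covariates are independent of outcomes
by construction, so CIs should cover RR = 1 at roughly the nominal rate —
scattered nominally significant associations are what multiple
comparisons produce under the null.
"""

from pathlib import Path

from vaxtiming.classify import classify_cohort
from vaxtiming.cohort import load_cohort
from vaxtiming.plots import plot_forest
from vaxtiming.risks import covariate_screen, demographics_table
from vaxtiming.schedule import zambia_epi_schedule

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    schedule = zambia_epi_schedule()
    cohort = load_cohort(ROOT / "cohort/roster.csv", ROOT / "cohort/visits.csv",
                         ROOT / "cohort/doses.csv")
    cls = classify_cohort(schedule, cohort)

    screen = covariate_screen(cohort, cls)
    screen.to_csv(ROOT / "risk_screen.csv", index=False)
    demo = demographics_table(cohort)
    demo.to_csv(ROOT / "demographics.csv", index=False)
    plot_forest(screen, ROOT / "risk_forest.png")

    print("demographics by attendance stratum (percent or median):")
    print(demo.to_string(index=False))
    sig = screen[screen["defined"] & ((screen["ci_low"] > 1) | (screen["ci_high"] < 1))]
    print(f"\nrisk screen: {len(screen)} covariate x outcome estimates; "
          f"{len(sig)} exclude RR=1 at 95%")
    cols = ["covariate", "outcome", "rr", "ci_low", "ci_high", "p_value"]
    print(screen[cols].round(3).to_string(index=False))


if __name__ == "__main__":
    main()
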