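#!/usr/bin/env python
"""Classify every attending infant's dose trajectory against the schedule.

Reads the cohort written by 01_simulate_cohort.py, applies the 6-10-14
week EPI windows, and reports the end-of-study dose distribution plus
how many infants lost up-to-date status in each window.
"""

from pathlib import Path

import pandas as pd

from vaxtiming.classify import classify_cohort, end_of_study_doses
from vaxtiming.cohort import load_cohort
from vaxtiming.schedule import zambia_epi_schedule

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    schedule = zambia_epi_schedule()
    cohort = load_cohort(ROOT / "cohort/roster.csv", ROOT / "cohort/visits.csv",
                         ROOT / "cohort/doses.csv")
    cls = classify_cohort(schedule, cohort)

    eos = end_of_study_doses(cls, schedule.n_doses)
    eos.to_csv(ROOT / "end_of_study.csv", index=False)
    rows = []
    for c in cls:
        row = {"infant_id": c.infant_id, "total_doses": c.total_doses}
        for ws in c.window_statuses:
            row[f"w{ws.window_index}_up_to_date"] = ws.up_to_date
            row[f"w{ws.window_index}_unvaccinated"] = ws.unvaccinated
        rows.append(row)
    per_infant = pd.DataFrame(rows)
    per_infant.to_csv(ROOT / "classifications.csv", index=False)

    print(f"classified {len(cls)} attending infants")
    print("end-of-study dose distribution:")
    print(eos.to_string(index=False))
    for k in range(1, schedule.n_doses + 1):
        utd = per_infant[f"w{k}_up_to_date"].mean()
        print(f"  up-to-date through window {k}: {100 * utd:.1f}% of attending")


if __name__ == "__main__":
    main()
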