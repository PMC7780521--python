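#!/usr/bin/env python
"""Window-stratified coverage tables and dose-timing histograms.

Produces the cumulative dose-by-window table, the per-window adherence
table (received / missed / compressed / up-to-date / unvaccinated, out of
each window's visitors) and the weekly timing, early-age and spacing
histograms, with plots.
"""

from pathlib import Path

from vaxtiming.classify import classify_cohort
from vaxtiming.cohort import attendance_profile, load_cohort
from vaxtiming.plots import plot_attendance_profile, plot_spacing_histogram, plot_weekly_timing
from vaxtiming.schedule import zambia_epi_schedule
from vaxtiming.tables import compression_summary, cumulative_table, timing_histograms, window_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    schedule = zambia_epi_schedule()
    cohort = load_cohort(ROOT / "cohort/roster.csv", ROOT / "cohort/visits.csv",
                         ROOT / "cohort/doses.csv")
    cls = classify_cohort(schedule, cohort)

    wt = window_table(schedule, cls)
    wt.to_csv(ROOT / "window_table.csv", index=False)
    ct = cumulative_table(schedule, cls)
    ct.per_range.reset_index(names="dose").to_csv(ROOT / "cumulative_per_range.csv", index=False)
    comp = compression_summary(cls)
    comp.to_csv(ROOT / "compression_summary.csv", index=False)
    hist = timing_histograms(schedule, cls)
    for name, df in hist.items():
        df.to_csv(ROOT / f"hist_{name}.csv", index=False)

    plot_attendance_profile(attendance_profile(cohort, 130), schedule, ROOT / "attendance.png")
    plot_weekly_timing(hist["weekly"], ROOT / "weekly_timing.png")
    if len(hist["spacing"]):
        plot_spacing_histogram(hist["spacing"], schedule.min_interval, ROOT / "spacing.png")

    print("window-stratified adherence (percent of each window's visitors):")
    cols = ["window_index", "visits", "received_pct", "missed_pct", "compressed_pct",
            "up_to_date_pct", "unvaccinated_pct"]
    print(wt[cols].to_string(index=False))
    print("\ncumulative first-receipt counts by age range:")
    print(ct.per_range.to_string())
    print("\nspacing violations (infant / event level):")
    print(comp.to_string(index=False))


if __name__ == "__main__":
    main()
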