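#!/usr/bin/env python
"""Dose-delay estimation under standard and worst-case censoring.

For each dose, estimates the cumulative administration-probability curve
two ways — the product-limit estimator, and the worst-case assumption
that infants lost to follow-up receive no further doses — and reads the
median / upper-quartile / upper-decile delays against the 42/70/98-day
targets.
"""

from pathlib import Path

import pandas as pd

from vaxtiming.cohort import load_cohort
from vaxtiming.delays import delay_quantiles, km_curve
from vaxtiming.plots import plot_delay_curves
from vaxtiming.schedule import zambia_epi_schedule

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    schedule = zambia_epi_schedule()
    cohort = load_cohort(ROOT / "cohort/roster.csv", ROOT / "cohort/visits.csv",
                         ROOT / "cohort/doses.csv")
    curves, frames, quants = [], [], []
    for dose in (1, 2, 3):
        for assumption in ("standard", "worst-case"):
            curve = km_curve(cohort, dose, assumption, schedule)
            frames.append(curve.as_frame()[1:])
            quants.append(delay_quantiles(curve, schedule).as_frame())
            if assumption == "worst-case":
                curves.append(curve)
    pd.concat(frames, ignore_index=True).to_csv(ROOT / "delay_curves.csv", index=False)
    qdf = pd.concat(quants, ignore_index=True)
    qdf.to_csv(ROOT / "delay_quantiles.csv", index=False)
    plot_delay_curves(curves, schedule, ROOT / "delay_curves.png")

    print("delay quantiles (days past target age; blank = never attained):")
    show = qdf.pivot_table(index=["dose_number", "assumption"], columns="quantile",
                           values="delay", aggfunc="first")
    print(show.to_string())
    wc = qdf[(qdf["assumption"] == "worst-case") & (qdf["quantile"] == 0.5)]
    print("\nworst-case median delays by dose:", wc["delay"].tolist())


if __name__ == "__main__":
    main()
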