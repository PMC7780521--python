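"""Coverage tables and timing histograms.

Produces the analysis's printed outputs from per-infant classifications:
the end-of-study dose distribution, the cumulative dose-by-window table,
the window-stratified adherence table, and the dose-timing histograms.

Percentages use the compatibility rounding convention of the printed
tables: one decimal place, ties rounded half away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .classify import TrajectoryClassification
from .schedule import ScheduleSpec, assign_window

__all__ = [
    "round_half_away",
    "percentage",
    "window_table",
    "CumulativeTable",
    "cumulative_table",
    "timing_histograms",
    "compression_summary",
]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero.

    This is the convention under which every printed percentage in the
    reference tables recomputes exactly from its numerator/denominator
    (banker's rounding does not).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """``100 * numerator / denominator`` under the table rounding convention."""
    if denominator == 0:
        return float("nan")
    return round_half_away(100.0 * numerator / denominator, ndigits)


def window_table(
    schedule: ScheduleSpec,
    classifications: list[TrajectoryClassification],
    n_attending: int | None = None,
) -> pd.DataFrame:
    """Window-stratified adherence table (one row per dose window).

    Denominators ("visits") are the unique infants with at least one
    scheduled visit whose age falls inside the window; received/missed,
    compressed, up-to-date and unvaccinated percentages are all out of
    that window's visitors.  ``unvaccinated_pct_attending`` additionally
    reports the unvaccinated count over the whole attending cohort, the
    denominator used when quoting population-level risk.
    """
    if n_attending is None:
        n_attending = len(classifications)
    rows = []
    for k, dose_spec in enumerate(schedule.doses, start=1):
        visitors = [c for c in classifications if c.window_statuses[k - 1].visited]
        nv = len(visitors)
        received = sum(1 for c in visitors if c.window_statuses[k - 1].received_dose)
        missed = nv - received
        compressed = sum(1 for c in visitors if c.compressed_in_window(k))
        utd = sum(1 for c in visitors if c.window_statuses[k - 1].up_to_date)
        unvax = sum(1 for c in visitors if c.window_statuses[k - 1].unvaccinated)
        rows.append(
            {
                "window_index": k,
                "age_range": f"{dose_spec.window_start}-{dose_spec.window_end}",
                "target_dose": k,
                "visits": nv,
                "received": received,
                "received_pct": percentage(received, nv),
                "missed": missed,
                "missed_pct": percentage(missed, nv),
                "compressed": compressed,
                "compressed_pct": percentage(compressed, nv),
                "up_to_date": utd,
                "up_to_date_pct": percentage(utd, nv),
                "unvaccinated": unvax,
                "unvaccinated_pct": percentage(unvax, nv),
                "unvaccinated_pct_attending": percentage(unvax, n_attending),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CumulativeTable:
    """Dose-receipt counts by age range plus per-window dose totals.

    ``per_range``: unique infants whose dose *k* was administered within
    each age range (early / window 1..n / after the last window) — the
    printed layout.  ``cumulative``: unique infants holding dose *k* by
    each window's end (non-decreasing across windows).
    ``doses_per_window``: total dose events administered within each
    range, any dose number (some infants receive more than one dose per
    window).
    """

    per_range: pd.DataFrame
    cumulative: pd.DataFrame
    doses_per_window: pd.Series


def cumulative_table(
    schedule: ScheduleSpec, classifications: list[TrajectoryClassification]
) -> CumulativeTable:
    ranges = ["early"] + [f"window{k}" for k in range(1, schedule.n_doses + 1)] + ["after"]

    def range_of(age: int) -> str:
        wa = assign_window(schedule, age)
        if wa.kind == "early":
            return "early"
        if wa.kind == "window":
            return f"window{wa.window_index}"
        if wa.kind == "gap":
            # between the early cutoff and window 1 (empty under default bounds)
            return "window1"
        return "after"

    per = pd.DataFrame(0, index=[d.label or f"dose{d.dose_number}" for d in schedule.doses], columns=ranges)
    totals = pd.Series(0, index=ranges)
    cum = pd.DataFrame(
        0,
        index=per.index,
        columns=[f"window{k}_end" for k in range(1, schedule.n_doses + 1)],
    )
    for c in classifications:
        for a in c.dose_assessments:
            r = range_of(a.admin_age)
            per.iloc[a.dose_number - 1, per.columns.get_loc(r)] += 1
            totals[r] += 1
            for k, d in enumerate(schedule.doses, start=1):
                if a.admin_age <= d.window_end:
                    cum.iloc[a.dose_number - 1, k - 1] += 1
    return CumulativeTable(per_range=per, cumulative=cum, doses_per_window=totals)


def timing_histograms(
    schedule: ScheduleSpec, classifications: list[TrajectoryClassification]
) -> dict[str, pd.DataFrame]:
    """Binned dose-timing series for plotting.

    ``weekly``: dose counts per week of age (week = floor(age / 7)), one
    column per dose number.  ``early_ages``: per-age counts of early
    doses.  ``spacing``: inter-dose gap counts per dose pair, split into
    compressed vs appropriately spaced.
    """
    weekly_rows, early_rows, spacing_rows = [], [], []
    for c in classifications:
        for a in c.dose_assessments:
            weekly_rows.append({"dose_number": a.dose_number, "week": a.admin_age // 7})
            if a.early:
                early_rows.append({"age": a.admin_age})
            if a.spacing_from_previous is not None:
                spacing_rows.append(
                    {
                        "dose_pair": f"{a.dose_number - 1}-{a.dose_number}",
                        "spacing": a.spacing_from_previous,
                        "compressed": a.compressed,
                    }
                )
    weekly = (
        pd.DataFrame(weekly_rows)
        .groupby(["dose_number", "week"])
        .size()
        .rename("count")
        .reset_index()
        if weekly_rows
        else pd.DataFrame(columns=["dose_number", "week", "count"])
    )
    early = (
        pd.DataFrame(early_rows).groupby("age").size().rename("count").reset_index()
        if early_rows
        else pd.DataFrame(columns=["age", "count"])
    )
    spacing = (
        pd.DataFrame(spacing_rows)
        .groupby(["dose_pair", "compressed", "spacing"])
        .size()
        .rename("count")
        .reset_index()
        if spacing_rows
        else pd.DataFrame(columns=["dose_pair", "compressed", "spacing", "count"])
    )
    return {"weekly": weekly, "early_ages": early, "spacing": spacing}


def compression_summary(
    classifications: list[TrajectoryClassification],
    thresholds: tuple[int, ...] = (28, 25, 20),
) -> pd.DataFrame:
    """Dose-spacing violations at several thresholds.

    For each threshold, reports both the number of infants with at least
    one inter-dose gap below it and the number of such gaps (events) —
    the two levels at which spacing violations can be quoted.
    """
    rows = []
    for t in thresholds:
        infants = 0
        events = 0
        for c in classifications:
            gaps = [
                a.spacing_from_previous
                for a in c.dose_assessments
                if a.spacing_from_previous is not None and a.spacing_from_previous < t
            ]
            events += len(gaps)
            infants += bool(gaps)
        rows.append({"threshold": t, "infants": infants, "events": events})
    return pd.DataFrame(rows)
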