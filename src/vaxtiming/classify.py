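"""Per-infant schedule-adherence classification.

The core state machine of the analysis: each attending infant's dose
trajectory is assessed against the schedule, producing per-dose flags
(early, compressed), per-window statuses (visited, received a dose,
up-to-date, unvaccinated) and end-of-study dose totals.

Classification rules
--------------------
* A dose is **early** if given at or before the early cutoff (before the
  first window opens).
* A dose is **compressed** if given less than the minimum interval after
  the preceding dose (never applies to dose 1).
* An infant is **up-to-date** at window *k* iff it possesses dose *k* by
  the end of window *k* and was up-to-date at window *k-1*.  Possession
  counts doses given early or in any prior window — the metric penalises
  lateness, not earliness — and once a window is missed, up-to-date
  status is never regained.
* An infant is **unvaccinated** at window *k* iff it has zero cumulative
  doses by the end of window *k*.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import CohortTables, attending_set, dose_ages, visit_ages
from .schedule import ScheduleSpec, assign_window

__all__ = [
    "DoseAssessment",
    "WindowStatus",
    "TrajectoryClassification",
    "classify_infant",
    "classify_cohort",
    "end_of_study_doses",
    "attending_unvaccinated_fraction",
]


@dataclass(frozen=True)
class DoseAssessment:
    dose_number: int
    admin_age: int
    window_kind: str  # early | window | gap | after
    window_index: int | None
    early: bool
    spacing_from_previous: int | None
    compressed: bool


@dataclass(frozen=True)
class WindowStatus:
    window_index: int
    visited: bool
    received_dose: bool
    up_to_date: bool
    unvaccinated: bool


@dataclass(frozen=True)
class TrajectoryClassification:
    infant_id: str
    dose_assessments: tuple[DoseAssessment, ...]
    window_statuses: tuple[WindowStatus, ...]
    total_doses: int
    cumulative_by_window_end: tuple[int, ...]

    def compressed_in_window(self, window_index: int) -> bool:
        return any(
            a.compressed and a.window_kind == "window" and a.window_index == window_index
            for a in self.dose_assessments
        )


def classify_infant(
    schedule: ScheduleSpec,
    infant_id: str,
    scheduled_visit_ages,
    dose_admin_ages,
) -> TrajectoryClassification:
    """Classify one infant's trajectory.

    Parameters
    ----------
    scheduled_visit_ages:
        Ages (days) of the infant's *scheduled* clinic visits; unscheduled
        or acute visits must be excluded by the caller, as window
        denominators count scheduled attendance only.
    dose_admin_ages:
        Administration ages (days) ordered by dose number 1..n, strictly
        increasing in age.
    """
    visit_set = sorted(int(a) for a in scheduled_visit_ages)
    doses = [int(a) for a in dose_admin_ages]
    if len(doses) > schedule.n_doses:
        raise ValueError(
            f"infant {infant_id!r}: {len(doses)} doses exceed the {schedule.n_doses}-dose schedule"
        )
    if any(b <= a for a, b in zip(doses, doses[1:])):
        raise ValueError(f"infant {infant_id!r}: dose ages must be strictly increasing")

    assessments = []
    for idx, age in enumerate(doses):
        wa = assign_window(schedule, age)
        spacing = age - doses[idx - 1] if idx > 0 else None
        assessments.append(
            DoseAssessment(
                dose_number=idx + 1,
                admin_age=age,
                window_kind=wa.kind,
                window_index=wa.window_index,
                early=age <= schedule.early_cutoff,
                spacing_from_previous=spacing,
                compressed=spacing is not None and spacing < schedule.min_interval,
            )
        )

    cumulative = tuple(sum(1 for a in doses if a <= d.window_end) for d in schedule.doses)

    statuses = []
    up_to_date = True
    for k, dose_spec in enumerate(schedule.doses, start=1):
        up_to_date = up_to_date and cumulative[k - 1] >= k
        statuses.append(
            WindowStatus(
                window_index=k,
                visited=any(dose_spec.contains(a) for a in visit_set),
                received_dose=any(dose_spec.contains(a) for a in doses),
                up_to_date=up_to_date,
                unvaccinated=cumulative[k - 1] == 0,
            )
        )

    return TrajectoryClassification(
        infant_id=infant_id,
        dose_assessments=tuple(assessments),
        window_statuses=tuple(statuses),
        total_doses=len(doses),
        cumulative_by_window_end=cumulative,
    )


def classify_cohort(
    schedule: ScheduleSpec,
    cohort: CohortTables,
    attending_only: bool = True,
) -> list[TrajectoryClassification]:
    """Classify every (attending) infant in the cohort, in roster order."""
    attendance = attending_set(cohort)
    keep = attendance["infant_id"][attendance["attended_any"]] if attending_only else attendance["infant_id"]
    keep_ids = list(keep)

    va = visit_ages(cohort)
    sched_visits = va[va["scheduled"]].groupby("infant_id")["age"].apply(list)
    da = dose_ages(cohort).sort_values(["infant_id", "dose_number"])
    dose_lists = da.groupby("infant_id")["age"].apply(list)

    out = []
    for iid in keep_ids:
        out.append(
            classify_infant(
                schedule,
                iid,
                sched_visits.get(iid, []),
                dose_lists.get(iid, []),
            )
        )
    return out


def end_of_study_doses(
    classifications: list[TrajectoryClassification], n_doses: int = 3
) -> pd.DataFrame:
    """End-of-study dose distribution: exact-N and at-least-N counts.

    Percentages are over the attending cohort (all classified infants),
    rounded to one decimal, half away from zero.
    """
    from .tables import percentage  # local import to avoid a cycle

    n = len(classifications)
    exact = {k: 0 for k in range(n_doses + 1)}
    for c in classifications:
        exact[min(c.total_doses, n_doses)] += 1
    rows = []
    running = n
    for k in range(n_doses + 1):
        at_least = sum(v for kk, v in exact.items() if kk >= k)
        rows.append(
            {
                "n_doses": k,
                "exact": exact[k],
                "exact_pct": percentage(exact[k], n) if n else float("nan"),
                "at_least": at_least,
                "at_least_pct": percentage(at_least, n) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def attending_unvaccinated_fraction(
    schedule: ScheduleSpec,
    cohort: CohortTables,
    classifications: list[TrajectoryClassification] | None = None,
) -> pd.DataFrame:
    """Hesitancy proxy: infants attending into each window with zero doses.

    For each window, counts infants whose last scheduled visit is at or
    after the window's start (they were still attending when the dose was
    due) yet who had received no dose by the window's end.  The fraction
    over those still-attending infants estimates the persistently
    hesitant core in a cohort where access is not limiting.
    """
    if classifications is None:
        classifications = classify_cohort(schedule, cohort)
    attendance = attending_set(cohort)
    last = attendance.set_index("infant_id")["last_visit_age"]
    rows = []
    for k, dose_spec in enumerate(schedule.doses, start=1):
        attending_ids = [c.infant_id for c in classifications if last.get(c.infant_id, -1) >= dose_spec.window_start]
        unvax = sum(
            1
            for c in classifications
            if last.get(c.infant_id, -1) >= dose_spec.window_start and c.cumulative_by_window_end[k - 1] == 0
        )
        denom = len(attending_ids)
        rows.append(
            {
                "window_index": k,
                "attending_into_window": denom,
                "unvaccinated": unvax,
                "fraction": unvax / denom if denom else float("nan"),
            }
        )
    return pd.DataFrame(rows)
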