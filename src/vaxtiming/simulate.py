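"""Synthetic birth-cohort generator.

Emulates the structure of a prospective urban birth cohort followed through
a 3-dose primary vaccination series: staggered calendar enrolment over
~10 months, enrolment at about one week of age, six scheduled clinic
visits at 2-4-week intervals through 14 weeks (attended visits may run
late, capped at 18 weeks), per-visit non-attendance, permanent dropout,
missed-visit rescheduling, a persistent hesitant subgroup that attends
but declines all doses, and dose administration constrained by minimum
age and minimum inter-dose interval plus a right-skewed readiness delay.

The generator returns standard :class:`~vaxtiming.cohort.CohortTables`
plus a ground-truth label table, so every downstream stage is testable
without any real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTables, validate_cohort
from .schedule import ScheduleSpec, zambia_epi_schedule

__all__ = ["SimConfig", "simulate_cohort", "realworld_config", "gamma_scale_for_median"]

#: Default scheduled visit ages (days). Three of the six visits coincide
#: with the 6/10/14-week dose targets.
DEFAULT_VISIT_OFFSETS = (21, 42, 56, 70, 84, 98)


def gamma_scale_for_median(shape: float, median: float) -> float:
    """Scale parameter giving a gamma(shape, scale) the requested median."""
    if median <= 0:
        return 0.0
    return float(median / stats.gamma.ppf(0.5, shape))


@dataclass(frozen=True)
class SimConfig:
    """All generator parameters.

    The defaults describe a fully adherent cohort (everyone attends every
    visit on time, no dropout, no hesitancy) with a small right-skewed
    dose-readiness delay; :func:`realworld_config` returns the preset that
    reproduces the qualitative shape of a real low-resource cohort.

    Parameters
    ----------
    n_infants:
        Number of enrolled infants.
    enrolment_span:
        Calendar span of study intake, days (staggered enrolment).
    enrolment_age_mean, enrolment_age_sd:
        Age at enrolment (days), truncated-normal around ~1 week.
    visit_offsets:
        Scheduled visit ages in days, strictly increasing.
    max_visit_age:
        Hard ceiling (days) on any attended visit (late final visits).
    per_visit_attendance_prob:
        Probability an on-study infant attends a given scheduled visit.
    dropout_hazard:
        Per-visit probability of permanent loss to follow-up (memoryless).
    never_attend_prob:
        Probability an enrollee attends no visits at all (initial
        disengagement; such infants are excluded as non-attending).
    reschedule_prob:
        Probability a missed visit is re-attempted 14 days later (once).
    hesitancy_fraction:
        Probability an infant attends normally but declines every dose.
    visit_lateness_median:
        Median lateness (days) of attended visits relative to schedule;
        gamma-distributed (shape 1.5), discretised, 0 disables.
    delay_shape, delay_median:
        Dose-readiness delay added to each dose's earliest eligible age:
        gamma(delay_shape) discretised with the given median; 0 disables.
    """

    n_infants: int = 1000
    enrolment_span: int = 300
    enrolment_age_mean: float = 7.0
    enrolment_age_sd: float = 2.0
    visit_offsets: tuple[int, ...] = DEFAULT_VISIT_OFFSETS
    max_visit_age: int = 126
    per_visit_attendance_prob: float = 1.0
    dropout_hazard: float = 0.0
    never_attend_prob: float = 0.0
    reschedule_prob: float = 0.0
    hesitancy_fraction: float = 0.0
    visit_lateness_median: float = 0.0
    delay_shape: float = 1.5
    delay_median: float = 2.0
    start_date: str = "2015-03-01"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.visit_offsets:
            raise ValueError("visit_offsets must not be empty")
        if list(self.visit_offsets) != sorted(set(self.visit_offsets)):
            raise ValueError("visit_offsets must be strictly increasing")
        for name in (
            "per_visit_attendance_prob",
            "dropout_hazard",
            "never_attend_prob",
            "reschedule_prob",
            "hesitancy_fraction",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.delay_median < 0 or self.visit_lateness_median < 0:
            raise ValueError("delay medians must be non-negative")
        if self.n_infants < 1:
            raise ValueError("n_infants must be >= 1")


def realworld_config(n_infants: int = 1500, seed: int = 0) -> SimConfig:
    """Preset emulating the qualitative shape of a real low-resource cohort.

    Roughly a quarter of enrollees never attend; attrition leaves about
    three-quarters of attenders on-study into the third dose window; a
    small hesitant core attends while declining vaccination; and dose
    delays are right-skewed and grow with dose number as the minimum
    inter-dose interval propagates earlier delays forward.
    """
    return SimConfig(
        n_infants=n_infants,
        never_attend_prob=0.24,
        per_visit_attendance_prob=0.90,
        dropout_hazard=0.05,
        reschedule_prob=0.8,
        hesitancy_fraction=0.07,
        visit_lateness_median=1.0,
        delay_median=0.5,
        seed=seed,
    )


def _discrete_gamma(rng: np.random.Generator, shape: float, median: float, size: int) -> np.ndarray:
    """Non-negative integer delays: floor of a gamma with the given median."""
    if median <= 0:
        return np.zeros(size, dtype=int)
    scale = gamma_scale_for_median(shape, median)
    return np.floor(rng.gamma(shape, scale, size=size)).astype(int)


def _simulate_infant(
    rng: np.random.Generator,
    config: SimConfig,
    schedule: ScheduleSpec,
    enrol_age: int,
    hesitant: bool,
    delays_row: np.ndarray,
) -> tuple[list[int], list[tuple[int, int]], int]:
    """One infant's visit-and-dose process.

    Scheduled visits may run late (gamma lateness); a missed visit may be
    re-attempted 14 days later (``reschedule_prob``); after each
    administered dose a follow-up appointment is booked at the minimum-
    interval mark if no later visit is already planned (routine EPI
    practice, and the reason final visits run as late as the visit-age
    ceiling); and when the next dose was not yet due at an attended visit,
    a make-up appointment may be booked for when it becomes due.  Dropout
    is a memoryless per-visit-attempt hazard and permanently ends the
    process.

    Returns (attended visit ages, [(dose_number, admin_age)], dropout
    attempt index or -1).
    """
    import heapq

    def lateness() -> int:
        return int(_discrete_gamma(rng, 1.5, config.visit_lateness_median, 1)[0])

    queue: list[int] = []
    for offset in config.visit_offsets:
        age = min(offset + lateness(), config.max_visit_age)
        if age > enrol_age:
            heapq.heappush(queue, age)

    attended: list[int] = []
    admin: list[tuple[int, int]] = []
    next_dose, prev_admin = 1, None
    dropout_visit, n_attempts = -1, 0
    while queue:
        age = heapq.heappop(queue)
        if queue and queue[0] == age:
            continue  # collapse same-day appointments
        if rng.random() < config.dropout_hazard:
            dropout_visit = n_attempts
            break
        n_attempts += 1
        if rng.random() >= config.per_visit_attendance_prob:
            makeup = min(age + 14, config.max_visit_age)
            if makeup > age and rng.random() < config.reschedule_prob:
                heapq.heappush(queue, makeup)
            continue
        attended.append(age)
        if hesitant or next_dose > schedule.n_doses:
            continue
        ready = schedule.min_age(next_dose, prev_admin) + int(delays_row[next_dose - 1])

        def covered(due: int) -> bool:
            # a planned visit already falls within a week of the due date
            return any(due <= q <= due + 7 for q in queue)

        if age >= ready:
            admin.append((next_dose, age))
            prev_admin = age
            next_dose += 1
            if next_dose <= schedule.n_doses:
                due = age + schedule.min_interval
                if due <= config.max_visit_age and not covered(due):
                    heapq.heappush(queue, min(due + lateness(), config.max_visit_age))
        elif ready <= config.max_visit_age and not covered(ready):
            if rng.random() < config.reschedule_prob:
                heapq.heappush(queue, min(ready + lateness(), config.max_visit_age))
    return sorted(set(attended)), admin, dropout_visit


def simulate_cohort(
    config: SimConfig, schedule: ScheduleSpec | None = None
) -> tuple[CohortTables, pd.DataFrame]:
    """Simulate a cohort under ``config``; reproducible for a fixed seed.

    Each infant attends scheduled visits subject to lateness, per-visit
    non-attendance, rescheduling and permanent dropout.  Dose ``k`` is
    administered at the first attended visit whose age reaches the dose's
    earliest eligible age (minimum first-dose age, or previous dose age
    plus the minimum interval) plus the sampled readiness delay; hesitant
    infants follow the same attendance process but receive no doses.

    Returns
    -------
    (cohort, truth):
        Validated :class:`CohortTables` and a ground-truth table with one
        row per infant (hesitant flag, dropout visit index or -1, never-
        attend flag, per-dose readiness delays and eligible ages).
    """
    if schedule is None:
        schedule = zambia_epi_schedule()
    rng = np.random.default_rng(config.seed)
    start = pd.Timestamp(config.start_date)
    n = config.n_infants
    n_doses = schedule.n_doses

    enrol_offsets = rng.integers(0, config.enrolment_span, size=n)
    enrol_ages = np.clip(
        np.rint(rng.normal(config.enrolment_age_mean, config.enrolment_age_sd, size=n)), 3, 21
    ).astype(int)
    hesitant = rng.random(n) < config.hesitancy_fraction
    never = rng.random(n) < config.never_attend_prob
    delays = np.column_stack(
        [_discrete_gamma(rng, config.delay_shape, config.delay_median, n) for _ in range(n_doses)]
    )

    roster_rows, visit_rows, dose_rows, truth_rows = [], [], [], []
    for i in range(n):
        iid = f"S{i:05d}"
        birth = start + pd.Timedelta(int(enrol_offsets[i]), "D")
        enrol = birth + pd.Timedelta(int(enrol_ages[i]), "D")
        roster_rows.append({"infant_id": iid, "birth_date": birth, "enrolment_date": enrol})

        if never[i]:
            attended, admin_events, dropout_visit = [], [], -1
        else:
            attended, admin_events, dropout_visit = _simulate_infant(
                rng, config, schedule, int(enrol_ages[i]), bool(hesitant[i]), delays[i]
            )
        for age in attended:
            visit_rows.append(
                {"infant_id": iid, "visit_date": birth + pd.Timedelta(age, "D"), "scheduled": True}
            )
        for dose_number, age in admin_events:
            dose_rows.append(
                {
                    "infant_id": iid,
                    "dose_number": dose_number,
                    "admin_date": birth + pd.Timedelta(age, "D"),
                }
            )

        truth_rows.append(
            {
                "infant_id": iid,
                "hesitant": bool(hesitant[i]),
                "never_attend": bool(never[i]) or not attended,
                "dropout_visit": dropout_visit,
                **{f"delay_dose{k+1}": int(delays[i, k]) for k in range(n_doses)},
            }
        )

    roster = pd.DataFrame(roster_rows)
    visits = pd.DataFrame(visit_rows, columns=["infant_id", "visit_date", "scheduled"])
    doses = pd.DataFrame(dose_rows, columns=["infant_id", "dose_number", "admin_date"])
    truth = pd.DataFrame(truth_rows)

    roster = _attach_covariates(roster, rng)
    cohort = validate_cohort(roster, visits, doses)
    return cohort, truth


def _attach_covariates(roster: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Binary/numeric demographic covariates, independent of outcomes.

    Marginal frequencies follow typical values for a periurban LMIC birth
    cohort (sex ~47% female, maternal HIV ~18%, facility birth mix, birth
    doses of BCG/OPV, maternal age, small-household counts).
    """
    n = len(roster)
    roster = roster.copy()
    roster["female"] = (rng.random(n) < 0.47).astype(int)
    roster["born_at_clinic"] = (rng.random(n) < 0.57).astype(int)
    roster["bcg_at_birth"] = (rng.random(n) < 0.46).astype(int)
    roster["opv_at_birth"] = (rng.random(n) < 0.33).astype(int)
    roster["maternal_hiv"] = (rng.random(n) < 0.18).astype(int)
    roster["maternal_art"] = (roster["maternal_hiv"] & (rng.random(n) < 0.9)).astype(int)
    roster["married"] = (rng.random(n) < 0.90).astype(int)
    roster["maternal_age"] = np.clip(np.rint(rng.normal(25.5, 5.0, n)), 18, 39).astype(int)
    roster["infants_in_house"] = 1 + rng.binomial(1, 0.1, n)
    roster["children_under5"] = 1 + rng.binomial(3, 0.3, n)
    roster["birth_weight_kg"] = np.round(np.clip(rng.normal(3.05, 0.35, n), 2.5, 4.5), 2)
    return roster
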