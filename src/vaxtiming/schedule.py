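"""Vaccine-schedule specification and age-window arithmetic.

The analysis classifies infant DTP doses against a national EPI schedule.
Each dose has a target age and an admissible age window; ages below the
first window are "early", and doses must respect a minimum inter-dose
interval.  The Zambian 6-10-14-week schedule ships as a built-in; other
schedules (e.g. a 2-4-6-month schedule) can be loaded from a YAML file.

Ages are whole-day differences between an event date and the birth date;
the day of birth is age 0.  All window bounds are closed (inclusive)
integer-day intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import yaml

__all__ = [
    "DoseSpec",
    "ScheduleSpec",
    "WindowAssignment",
    "zambia_epi_schedule",
    "assign_window",
    "load_schedule",
    "save_schedule",
]


@dataclass(frozen=True)
class DoseSpec:
    """One scheduled dose: target age and admissible window (days, inclusive)."""

    dose_number: int
    target_age: int
    window_start: int
    window_end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.dose_number < 1:
            raise ValueError(f"dose_number must be >= 1, got {self.dose_number}")
        if not (self.window_start <= self.target_age <= self.window_end):
            raise ValueError(
                f"dose {self.dose_number}: target age {self.target_age} outside "
                f"window [{self.window_start}, {self.window_end}]"
            )

    def contains(self, age: int) -> bool:
        return self.window_start <= age <= self.window_end


@dataclass(frozen=True)
class ScheduleSpec:
    """An ordered multi-dose schedule with spacing and early-dose rules.

    Parameters
    ----------
    doses:
        Ordered dose specifications with non-overlapping, increasing windows.
    min_first_age:
        Minimum administration age (days) for dose 1.
    min_interval:
        Minimum spacing (days) between consecutive doses; doses given
        closer than this are "compressed".
    early_cutoff:
        Ages ``<= early_cutoff`` are "early" (before the first window).
    """

    doses: tuple[DoseSpec, ...]
    min_first_age: int
    min_interval: int
    early_cutoff: int
    name: str = "custom"

    def __post_init__(self) -> None:
        if not self.doses:
            raise ValueError("schedule must define at least one dose")
        object.__setattr__(self, "doses", tuple(self.doses))
        numbers = [d.dose_number for d in self.doses]
        if numbers != list(range(1, len(self.doses) + 1)):
            raise ValueError(f"dose numbers must be 1..{len(self.doses)}, got {numbers}")
        for prev, nxt in zip(self.doses, self.doses[1:]):
            if nxt.window_start <= prev.window_end:
                raise ValueError(
                    f"windows of doses {prev.dose_number} and {nxt.dose_number} "
                    "overlap or are out of order"
                )
        if self.min_interval <= 0:
            raise ValueError("min_interval must be positive")
        if self.early_cutoff >= self.doses[0].window_start:
            raise ValueError("early_cutoff must precede the first window")

    @property
    def n_doses(self) -> int:
        return len(self.doses)

    def dose(self, dose_number: int) -> DoseSpec:
        try:
            spec = self.doses[dose_number - 1]
        except IndexError:
            raise KeyError(f"schedule has no dose {dose_number}") from None
        return spec

    @property
    def last_window_end(self) -> int:
        return self.doses[-1].window_end

    def min_age(self, dose_number: int, previous_admin_age: int | None) -> int:
        """Earliest admissible age for a dose given the previous dose's age."""
        if dose_number == 1:
            return self.min_first_age
        if previous_admin_age is None:
            raise ValueError(f"dose {dose_number} requires a previous administration age")
        return previous_admin_age + self.min_interval


@dataclass(frozen=True)
class WindowAssignment:
    """Where an age falls relative to the schedule's windows."""

    kind: Literal["early", "window", "gap", "after"]
    window_index: int | None = None

    @property
    def in_window(self) -> bool:
        return self.kind == "window"


def zambia_epi_schedule(window3_end: int = 127) -> ScheduleSpec:
    """The Zambian 6-10-14-week EPI schedule for the 3-dose DTP series.

    Targets 42/70/98 days with windows [41, 69], [70, 97], [98, window3_end];
    window 1 opens one day before the 6-week target to absorb uncertainty in
    the exact timing of birth and vaccination.  Ages 0-40 are early.  The
    last window's upper bound defaults to 127 days and is configurable
    (126 is the other printed convention).
    """
    if window3_end < 98:
        raise ValueError("window3_end must be >= 98")
    return ScheduleSpec(
        doses=(
            DoseSpec(1, 42, 41, 69, "DTP1"),
            DoseSpec(2, 70, 70, 97, "DTP2"),
            DoseSpec(3, 98, 98, window3_end, "DTP3"),
        ),
        min_first_age=42,
        min_interval=28,
        early_cutoff=40,
        name="zambia-epi-6-10-14",
    )


def assign_window(schedule: ScheduleSpec, age: int) -> WindowAssignment:
    """Map an age in days onto the schedule: early, a dose window, a gap, or after.

    Total and deterministic for every non-negative integer age; window
    boundaries are inclusive on both ends.
    """
    age = int(age)
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    if age <= schedule.early_cutoff:
        return WindowAssignment("early")
    for dose in schedule.doses:
        if age < dose.window_start:
            return WindowAssignment("gap")
        if age <= dose.window_end:
            return WindowAssignment("window", dose.dose_number)
    return WindowAssignment("after")


def _schedule_to_dict(schedule: ScheduleSpec) -> dict:
    return {
        "name": schedule.name,
        "min_first_age": schedule.min_first_age,
        "min_interval": schedule.min_interval,
        "early_cutoff": schedule.early_cutoff,
        "doses": [
            {
                "dose_number": d.dose_number,
                "target_age": d.target_age,
                "window_start": d.window_start,
                "window_end": d.window_end,
                "label": d.label,
            }
            for d in schedule.doses
        ],
    }


def save_schedule(schedule: ScheduleSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_schedule_to_dict(schedule), fh, sort_keys=False)


def load_schedule(source) -> ScheduleSpec:
    """Load a schedule from a YAML file path or a pre-parsed mapping."""
    if isinstance(source, dict):
        data = source
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh)
    doses = tuple(
        DoseSpec(
            dose_number=int(d["dose_number"]),
            target_age=int(d["target_age"]),
            window_start=int(d["window_start"]),
            window_end=int(d["window_end"]),
            label=str(d.get("label", "")),
        )
        for d in data["doses"]
    )
    return ScheduleSpec(
        doses=doses,
        min_first_age=int(data["min_first_age"]),
        min_interval=int(data["min_interval"]),
        early_cutoff=int(data["early_cutoff"]),
        name=str(data.get("name", "custom")),
    )
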