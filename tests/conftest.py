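"""Shared fixtures: a hand-buildable cohort and the built-in schedule."""

from __future__ import annotations

import pandas as pd
import pytest

from vaxtiming.cohort import CohortTables, validate_cohort
from vaxtiming.schedule import zambia_epi_schedule

BASE = pd.Timestamp("2015-03-01")


def build_cohort(infants: dict[str, dict]) -> CohortTables:
    """Build a validated cohort from per-infant age specifications.

    ``infants`` maps infant_id -> dict with optional keys ``enrol_age``
    (default 7), ``visit_ages`` (scheduled visits), ``unscheduled_ages``,
    ``dose_ages`` (ordered ages of doses 1..k), ``birth_offset`` (calendar
    stagger, days) and any extra covariate columns.
    """
    roster_rows, visit_rows, dose_rows = [], [], []
    for n, (iid, spec) in enumerate(infants.items()):
        birth = BASE + pd.Timedelta(spec.get("birth_offset", 11 * n), "D")
        covs = {
            k: v
            for k, v in spec.items()
            if k not in {"enrol_age", "visit_ages", "unscheduled_ages", "dose_ages", "birth_offset"}
        }
        roster_rows.append(
            {
                "infant_id": iid,
                "birth_date": birth,
                "enrolment_date": birth + pd.Timedelta(spec.get("enrol_age", 7), "D"),
                **covs,
            }
        )
        for age in spec.get("visit_ages", []):
            visit_rows.append(
                {"infant_id": iid, "visit_date": birth + pd.Timedelta(age, "D"), "scheduled": True}
            )
        for age in spec.get("unscheduled_ages", []):
            visit_rows.append(
                {"infant_id": iid, "visit_date": birth + pd.Timedelta(age, "D"), "scheduled": False}
            )
        for k, age in enumerate(spec.get("dose_ages", []), start=1):
            dose_rows.append(
                {"infant_id": iid, "dose_number": k, "admin_date": birth + pd.Timedelta(age, "D")}
            )
    roster = pd.DataFrame(roster_rows)
    visits = pd.DataFrame(visit_rows, columns=["infant_id", "visit_date", "scheduled"])
    doses = pd.DataFrame(dose_rows, columns=["infant_id", "dose_number", "admin_date"])
    return validate_cohort(roster, visits, doses)


@pytest.fixture(scope="session")
def schedule():
    return zambia_epi_schedule()
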