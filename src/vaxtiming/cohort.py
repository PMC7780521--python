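"""Cohort tables: loading, validation, attendance intervals, deidentification.

The pipeline's common input is a bundle of three delimited-text tables:

``roster``
    One row per enrolled infant: ``infant_id``, ``birth_date``,
    ``enrolment_date`` (ISO-8601 dates) plus any number of covariate
    columns (binary flags or small integers/floats).
``visits``
    One row per clinic visit: ``infant_id``, ``visit_date``, ``scheduled``
    (boolean; routine study visits vs acute/unscheduled care).
``doses``
    One row per administered DTP dose: ``infant_id``, ``dose_number``
    (1..n), ``admin_date``.  Dose events need not coincide with a visit
    (doses can be back-filled from vaccine-card review).

All analysis runs on integer ages (event date minus birth date, in days;
day of birth is age 0), which makes every downstream statistic invariant
under the per-infant date jitter used to deidentify the study data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortTables",
    "CohortValidationError",
    "load_cohort",
    "save_cohort",
    "validate_cohort",
    "attending_set",
    "attending_at_age",
    "attendance_profile",
    "deidentify",
    "visit_ages",
    "dose_ages",
]

ROSTER_REQUIRED = ("infant_id", "birth_date", "enrolment_date")
VISIT_REQUIRED = ("infant_id", "visit_date", "scheduled")
DOSE_REQUIRED = ("infant_id", "dose_number", "admin_date")


class CohortValidationError(ValueError):
    """Raised when the cohort tables violate the input contract.

    ``problems`` lists every violation found, each with row context.
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            f"{len(self.problems)} validation problem(s):\n" + "\n".join(f"  - {p}" for p in self.problems)
        )


@dataclass
class CohortTables:
    """Validated roster + visit events + dose events."""

    roster: pd.DataFrame
    visits: pd.DataFrame
    doses: pd.DataFrame

    @property
    def n_enrolled(self) -> int:
        return len(self.roster)

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.roster.columns if c not in ROSTER_REQUIRED]

    def copy(self) -> "CohortTables":
        return CohortTables(self.roster.copy(), self.visits.copy(), self.doses.copy())


def _parse_dates(df: pd.DataFrame, columns, table: str, problems: list[str]) -> pd.DataFrame:
    df = df.copy()
    for col in columns:
        parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        for i in bad[:10]:
            problems.append(f"{table} row {i}: unparseable date {df.at[i, col]!r} in column {col!r}")
        if df[col].isna().any():
            for i in df.index[df[col].isna()][:10]:
                problems.append(f"{table} row {i}: missing date in column {col!r}")
        df[col] = parsed
    return df


def validate_cohort(roster: pd.DataFrame, visits: pd.DataFrame, doses: pd.DataFrame) -> CohortTables:
    """Validate the three tables and return the bundle.

    Enforces: required columns present, parseable ISO dates, unique infant
    ids, referential integrity (every event's infant exists in the roster),
    enrolment/visit dates not before birth, and per-infant dose numbers
    unique with administration dates strictly increasing in dose number.
    Raises :class:`CohortValidationError` listing every problem found.
    """
    problems: list[str] = []
    for name, df, required in (
        ("roster", roster, ROSTER_REQUIRED),
        ("visits", visits, VISIT_REQUIRED),
        ("doses", doses, DOSE_REQUIRED),
    ):
        missing = [c for c in required if c not in df.columns]
        if missing:
            problems.append(f"{name}: missing required column(s) {missing}")
    if problems:
        raise CohortValidationError(problems)

    roster = _parse_dates(roster, ["birth_date", "enrolment_date"], "roster", problems)
    visits = _parse_dates(visits, ["visit_date"], "visits", problems)
    doses = _parse_dates(doses, ["admin_date"], "doses", problems)
    if problems:
        raise CohortValidationError(problems)

    dup = roster["infant_id"][roster["infant_id"].duplicated()]
    for iid in dup.unique()[:10]:
        problems.append(f"roster: duplicate infant_id {iid!r}")

    known = set(roster["infant_id"])
    for name, df in (("visits", visits), ("doses", doses)):
        orphan = df.loc[~df["infant_id"].isin(known), "infant_id"]
        for iid in orphan.unique()[:10]:
            problems.append(f"{name}: infant_id {iid!r} not present in roster")

    birth = roster.set_index("infant_id")["birth_date"]
    bad_enrol = roster[roster["enrolment_date"] < roster["birth_date"]]
    for _, row in bad_enrol.iterrows():
        problems.append(f"roster: infant {row['infant_id']!r} enrolled before birth")

    v = visits[visits["infant_id"].isin(known)]
    vb = v["infant_id"].map(birth)
    for i in v.index[v["visit_date"] < vb][:10]:
        problems.append(f"visits row {i}: visit before birth for infant {v.at[i, 'infant_id']!r}")

    d = doses[doses["infant_id"].isin(known)].copy()
    if not d.empty:
        d["dose_number"] = pd.to_numeric(d["dose_number"], errors="coerce")
        for i in d.index[d["dose_number"].isna() | (d["dose_number"] < 1)][:10]:
            problems.append(f"doses row {i}: invalid dose_number for infant {d.at[i, 'infant_id']!r}")
        d = d.dropna(subset=["dose_number"])
        for iid, grp in d.groupby("infant_id", sort=False):
            if grp["dose_number"].duplicated().any():
                problems.append(f"doses: infant {iid!r} has duplicate dose_number")
                continue
            g = grp.sort_values("dose_number")
            if not g["admin_date"].is_monotonic_increasing or g["admin_date"].duplicated().any():
                problems.append(
                    f"doses: infant {iid!r} administration dates not strictly increasing with dose_number"
                )
        db = d["infant_id"].map(birth)
        for i in d.index[d["admin_date"] < db][:10]:
            problems.append(f"doses row {i}: dose before birth for infant {d.at[i, 'infant_id']!r}")

    if problems:
        raise CohortValidationError(problems)

    visits = visits.copy()
    visits["scheduled"] = visits["scheduled"].astype(bool)
    doses = doses.copy()
    doses["dose_number"] = doses["dose_number"].astype(int)
    return CohortTables(roster.reset_index(drop=True), visits.reset_index(drop=True), doses.reset_index(drop=True))


def load_cohort(roster_path, visits_path, doses_path) -> CohortTables:
    """Read and validate the three comma-separated cohort tables."""
    roster = pd.read_csv(roster_path, dtype={"infant_id": str})
    visits = pd.read_csv(visits_path, dtype={"infant_id": str})
    doses = pd.read_csv(doses_path, dtype={"infant_id": str})
    return validate_cohort(roster, visits, doses)


def save_cohort(cohort: CohortTables, out_dir) -> dict[str, Path]:
    """Write the three tables as CSV under ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df, date_cols in (
        ("roster", cohort.roster, ["birth_date", "enrolment_date"]),
        ("visits", cohort.visits, ["visit_date"]),
        ("doses", cohort.doses, ["admin_date"]),
    ):
        df = df.copy()
        for c in date_cols:
            df[c] = pd.to_datetime(df[c]).dt.strftime("%Y-%m-%d")
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths


def visit_ages(cohort: CohortTables) -> pd.DataFrame:
    """Per visit: infant_id, age (days), scheduled flag."""
    birth = cohort.roster.set_index("infant_id")["birth_date"]
    out = cohort.visits.copy()
    out["age"] = (out["visit_date"] - out["infant_id"].map(birth)).dt.days.astype(int)
    return out[["infant_id", "age", "scheduled"]]


def dose_ages(cohort: CohortTables) -> pd.DataFrame:
    """Per dose event: infant_id, dose_number, age (days)."""
    birth = cohort.roster.set_index("infant_id")["birth_date"]
    out = cohort.doses.copy()
    out["age"] = (out["admin_date"] - out["infant_id"].map(birth)).dt.days.astype(int)
    return out[["infant_id", "dose_number", "age"]]


def attending_set(cohort: CohortTables) -> pd.DataFrame:
    """Per-infant attendance interval and attending flag.

    An infant is *attending* if it has at least one scheduled clinic visit;
    attending infants are on-study from enrolment until their last recorded
    visit.  Never-attending enrollees are excluded from all downstream
    analysis.  Returns one row per roster infant with columns
    ``infant_id, attended_any, n_scheduled_visits, enrol_age,
    first_visit_age, last_visit_age``.
    """
    birth = cohort.roster.set_index("infant_id")["birth_date"]
    va = visit_ages(cohort)
    sched = va[va["scheduled"]]
    agg = sched.groupby("infant_id")["age"].agg(["min", "max", "count"])
    out = cohort.roster[["infant_id"]].copy()
    out["enrol_age"] = (cohort.roster["enrolment_date"] - cohort.roster["birth_date"]).dt.days.astype(int)
    out["n_scheduled_visits"] = out["infant_id"].map(agg["count"]).fillna(0).astype(int)
    out["attended_any"] = out["n_scheduled_visits"] > 0
    out["first_visit_age"] = out["infant_id"].map(agg["min"])
    out["last_visit_age"] = out["infant_id"].map(agg["max"])
    return out


def attending_at_age(cohort: CohortTables, age: int, attendance: pd.DataFrame | None = None) -> int:
    """Number of attending infants whose on-study interval covers ``age``.

    The on-study interval is [enrolment age, last scheduled-visit age].
    """
    if attendance is None:
        attendance = attending_set(cohort)
    att = attendance[attendance["attended_any"]]
    return int(((att["enrol_age"] <= age) & (att["last_visit_age"] >= age)).sum())


def attendance_profile(cohort: CohortTables, max_age: int = 130) -> pd.DataFrame:
    """Attending-infant count at each age 0..max_age (study-participation curve)."""
    attendance = attending_set(cohort)
    att = attendance[attendance["attended_any"]]
    ages = np.arange(max_age + 1)
    enrol = att["enrol_age"].to_numpy()[:, None]
    last = att["last_visit_age"].to_numpy()[:, None]
    counts = ((enrol <= ages) & (last >= ages)).sum(axis=0)
    return pd.DataFrame({"age": ages, "attending": counts})


def deidentify(cohort: CohortTables, max_offset: int = 3, seed: int = 0) -> CohortTables:
    """Shift every date of each infant by one per-infant uniform offset.

    Each infant draws an integer offset from [-max_offset, +max_offset]
    (inclusive) and the same offset is applied to its birth, enrolment,
    visit and dose dates, so all within-infant ages are unchanged.
    Deterministic for a fixed seed.
    """
    if max_offset < 0:
        raise ValueError("max_offset must be >= 0")
    rng = np.random.default_rng(seed)
    ids = cohort.roster["infant_id"].tolist()
    offsets = pd.Series(
        rng.integers(-max_offset, max_offset + 1, size=len(ids)), index=ids, dtype=int
    )

    def shift(df: pd.DataFrame, date_cols: list[str]) -> pd.DataFrame:
        df = df.copy()
        delta = df["infant_id"].map(offsets).to_numpy()
        for c in date_cols:
            df[c] = df[c] + pd.to_timedelta(delta, unit="D")
        return df

    return CohortTables(
        roster=shift(cohort.roster, ["birth_date", "enrolment_date"]),
        visits=shift(cohort.visits, ["visit_date"]),
        doses=shift(cohort.doses, ["admin_date"]),
    )
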