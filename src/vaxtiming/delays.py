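"""Age-to-vaccination curves under two censoring assumptions, and delay quantiles.

For each dose we estimate the cumulative probability that an infant has
received the dose by a given age.  Infants without the dose are censored
at their last scheduled visit, and two assumptions are offered:

``standard``
    The product-limit (Kaplan-Meier) estimator: censored infants are
    assumed to be vaccinated at the same age-specific rate as those still
    observed.  Cumulative probability is 1 - S(age).
``worst-case``
    Infants lost to follow-up receive no further vaccinations: the curve
    is simply (infants with the dose by age a) / (all attending infants).
    This floors the estimate; the worst-case curve never exceeds the
    standard one.

Delay quantiles read the curve against the dose's target age: the delay
at quantile *q* is the first age at which the curve reaches *q*, minus
the target age.  A quantile may never be attained (e.g. the slowest
decile of a dose that more than 10% of the cohort never receives).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .cohort import CohortTables, attending_set, dose_ages
from .schedule import ScheduleSpec

__all__ = [
    "DelayCurve",
    "DelayQuantiles",
    "dose_durations",
    "km_curve",
    "delay_quantiles",
]

ASSUMPTIONS = ("standard", "worst-case")


@dataclass
class DelayCurve:
    """Step function of age -> cumulative dose-administration probability."""

    assumption: str
    dose_number: int
    ages: np.ndarray  # step-change ages, increasing
    cum_prob: np.ndarray  # P(dose received by age), non-decreasing in [0, 1]
    n: int  # attending infants contributing
    n_events: int
    durations: np.ndarray  # per-infant event/censor ages
    observed: np.ndarray  # per-infant event indicator

    def prob_at(self, age: float) -> float:
        """Curve value at ``age`` (right-continuous step function)."""
        idx = np.searchsorted(self.ages, age, side="right") - 1
        return float(self.cum_prob[idx]) if idx >= 0 else 0.0

    def at_risk_table(self, ages) -> pd.DataFrame:
        """Number still at risk (no dose, not yet censored) at chosen ages."""
        return pd.DataFrame(
            {"age": list(ages), "at_risk": [int((self.durations >= a).sum()) for a in ages]}
        )

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "cum_prob": self.cum_prob,
                "assumption": self.assumption,
                "dose_number": self.dose_number,
            }
        )


@dataclass
class DelayQuantiles:
    dose_number: int
    assumption: str
    target_age: int
    quantiles: dict[float, dict]  # q -> {"attained": bool, "age": int|None, "delay": int|None}

    def delay(self, q: float):
        return self.quantiles[q]["delay"]

    def attained(self, q: float) -> bool:
        return self.quantiles[q]["attained"]

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "dose_number": self.dose_number,
                "assumption": self.assumption,
                "quantile": q,
                "attained": v["attained"],
                "age": v["age"],
                "delay": v["delay"],
            }
            for q, v in self.quantiles.items()
        ]
        return pd.DataFrame(rows)


def dose_durations(
    cohort: CohortTables, dose_number: int, attendance: pd.DataFrame | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(durations, event_observed) for one dose over the attending cohort.

    Duration is the dose administration age for vaccinated infants, else
    the last scheduled-visit age (censoring).  Dose events recorded after
    the last visit (card review) count as events at their admin age.
    """
    if attendance is None:
        attendance = attending_set(cohort)
    att = attendance[attendance["attended_any"]]
    da = dose_ages(cohort)
    da = da[da["dose_number"] == dose_number].set_index("infant_id")["age"]
    event_age = att["infant_id"].map(da)
    observed = event_age.notna().to_numpy()
    durations = np.where(observed, event_age.to_numpy(dtype=float), att["last_visit_age"].to_numpy(dtype=float))
    return durations, observed


def km_curve(
    cohort: CohortTables,
    dose_number: int,
    assumption: str = "worst-case",
    schedule: ScheduleSpec | None = None,
    attendance: pd.DataFrame | None = None,
) -> DelayCurve:
    """Cumulative dose-administration probability vs age for one dose."""
    if assumption not in ASSUMPTIONS:
        raise ValueError(f"assumption must be one of {ASSUMPTIONS}, got {assumption!r}")
    if schedule is not None and not 1 <= dose_number <= schedule.n_doses:
        raise ValueError(f"dose_number {dose_number} outside the {schedule.n_doses}-dose schedule")
    durations, observed = dose_durations(cohort, dose_number, attendance)
    return km_curve_from_durations(durations, observed, dose_number, assumption)


def km_curve_from_durations(
    durations: np.ndarray, observed: np.ndarray, dose_number: int, assumption: str
) -> DelayCurve:
    """Build a curve from raw (duration, event) pairs.

    Ties between an event and a censoring at the same age follow the
    standard convention: the event happens first (the censored infant is
    still in the risk set at that age).
    """
    durations = np.asarray(durations, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    n = len(durations)
    if n == 0:
        raise ValueError("no attending infants")
    event_ages = np.unique(durations[observed])
    if assumption == "worst-case":
        # censoring is treated as never-event: empirical fraction over all n
        cum = np.array([(durations[observed] <= a).sum() / n for a in event_ages])
    else:
        kmf = KaplanMeierFitter()
        kmf.fit(durations, event_observed=observed)
        surv = kmf.survival_function_at_times(event_ages).to_numpy()
        cum = 1.0 - surv
    ages = np.concatenate([[-np.inf], event_ages])
    probs = np.concatenate([[0.0], cum])
    return DelayCurve(
        assumption=assumption,
        dose_number=dose_number,
        ages=ages,
        cum_prob=probs,
        n=n,
        n_events=int(observed.sum()),
        durations=durations,
        observed=observed,
    )


def delay_quantiles(
    curve: DelayCurve,
    schedule: ScheduleSpec,
    quantiles: tuple[float, ...] = (0.5, 0.75, 0.9),
) -> DelayQuantiles:
    """Delays of the median / upper-quartile / upper-decile infant.

    Quantile inversion is the left-continuous generalised inverse: the
    smallest observed age at which the curve reaches *q*.  Infants
    vaccinated before the target age yield negative delays, which are
    preserved.  If the curve never reaches *q* the quantile is flagged
    unattained with an undefined delay.
    """
    target = schedule.dose(curve.dose_number).target_age
    out: dict[float, dict] = {}
    for q in quantiles:
        reached = np.nonzero(curve.cum_prob >= q - 1e-12)[0]
        if len(reached) == 0 or not np.isfinite(curve.ages[reached[0]]):
            out[q] = {"attained": False, "age": None, "delay": None}
        else:
            age = int(curve.ages[reached[0]])
            out[q] = {"attained": True, "age": age, "delay": age - target}
    return DelayQuantiles(
        dose_number=curve.dose_number,
        assumption=curve.assumption,
        target_age=target,
        quantiles=out,
    )
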