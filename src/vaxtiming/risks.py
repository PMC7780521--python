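"""Relative-risk screening of demographic covariates and the demographics table.

End-of-study vaccination outcomes (unvaccinated, at least one dose, full
series) are screened against binary covariates with unadjusted relative
risks.  The 95% CI is the Katz log-scale normal interval

    exp( ln RR  +/-  1.96 * sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)) )

with a two-sided Wald p-value on ln RR.  No multiplicity correction is
applied: the screen is descriptive, and associations of the size seen in
wide covariate grids are expected under sampling variation alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import TrajectoryClassification
from .cohort import CohortTables, attending_set

__all__ = [
    "RiskEstimate",
    "relative_risk",
    "outcome_frame",
    "covariate_screen",
    "demographics_table",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class RiskEstimate:
    covariate: str
    outcome: str
    a: float  # exposed, outcome-positive
    b: float  # exposed, outcome-negative
    c: float  # unexposed, outcome-positive
    d: float  # unexposed, outcome-negative
    rr: float
    ci_low: float
    ci_high: float
    p_value: float
    continuity_corrected: bool = False
    defined: bool = True


def relative_risk(a: int, b: int, c: int, d: int, covariate: str = "", outcome: str = "") -> RiskEstimate:
    """Relative risk of the outcome in exposed (a, b) vs unexposed (c, d).

    A zero cell triggers the Haldane-Anscombe correction (0.5 added to
    all four cells, flagged on the estimate).  A zero margin (no exposed
    or no unexposed individuals, or no outcome events at all) leaves the
    RR undefined.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0:
        return RiskEstimate(covariate, outcome, a, b, c, d, float("nan"), float("nan"),
                            float("nan"), float("nan"), defined=False)
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d)) if corrected else (a, b, c, d)
    rr = (aa / (aa + bb)) / (cc / (cc + dd))
    se = np.sqrt(1 / aa - 1 / (aa + bb) + 1 / cc - 1 / (cc + dd))
    log_rr = np.log(rr)
    ci_low = float(np.exp(log_rr - Z95 * se))
    ci_high = float(np.exp(log_rr + Z95 * se))
    p = float(2 * stats.norm.sf(abs(log_rr) / se)) if se > 0 else float("nan")
    return RiskEstimate(covariate, outcome, a, b, c, d, float(rr), ci_low, ci_high, p,
                        continuity_corrected=corrected)


DEFAULT_OUTCOMES = ("unvaccinated", "at_least_1_dose", "all_doses")


def outcome_frame(
    classifications: list[TrajectoryClassification], n_doses: int = 3
) -> pd.DataFrame:
    """Per-infant binary end-of-study outcomes (indexed by infant_id)."""
    rows = [
        {
            "infant_id": c.infant_id,
            "unvaccinated": c.total_doses == 0,
            "at_least_1_dose": c.total_doses >= 1,
            "all_doses": c.total_doses >= n_doses,
        }
        for c in classifications
    ]
    return pd.DataFrame(rows).set_index("infant_id")


def _binary_coding(series: pd.Series, covariate: str) -> pd.Series:
    """Coerce a covariate to 0/1; numeric covariates split at their median."""
    s = series.dropna()
    values = set(s.unique())
    if values <= {0, 1} or values <= {False, True}:
        return series.astype(float)
    if pd.api.types.is_numeric_dtype(series):
        med = s.median()
        return (series > med).astype(float)
    raise ValueError(f"covariate {covariate!r} is not binary and has no numeric coding")


def covariate_screen(
    cohort: CohortTables,
    classifications: list[TrajectoryClassification],
    covariates: list[str] | None = None,
    outcomes: tuple[str, ...] = DEFAULT_OUTCOMES,
) -> pd.DataFrame:
    """Full covariate-by-outcome grid of unadjusted relative risks.

    Covariates default to every roster column beyond the identifiers.
    Numeric covariates are dichotomised at their median (above vs at-or-
    below), a coding recorded in the ``coding`` column.
    """
    if covariates is None:
        covariates = cohort.covariate_columns
    out = outcome_frame(classifications)
    roster = cohort.roster.set_index("infant_id").loc[out.index]
    rows = []
    for cov in covariates:
        series = _binary_coding(roster[cov], cov)
        coding = "binary" if set(roster[cov].dropna().unique()) <= {0, 1, False, True} else "above-median"
        for outcome in outcomes:
            y = out[outcome].astype(bool)
            x = series.loc[y.index]
            mask = x.notna()
            a = int((y[mask] & (x[mask] == 1)).sum())
            b = int((~y[mask] & (x[mask] == 1)).sum())
            c = int((y[mask] & (x[mask] == 0)).sum())
            d = int((~y[mask] & (x[mask] == 0)).sum())
            est = relative_risk(a, b, c, d, covariate=cov, outcome=outcome)
            rows.append(
                {
                    "covariate": cov,
                    "outcome": outcome,
                    "coding": coding,
                    "a": a, "b": b, "c": c, "d": d,
                    "rr": est.rr,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "p_value": est.p_value,
                    "continuity_corrected": est.continuity_corrected,
                    "defined": est.defined,
                }
            )
    return pd.DataFrame(rows)


def demographics_table(
    cohort: CohortTables,
    n_scheduled_visits: int = 6,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Covariate summaries stratified by duration of study attendance.

    Three nested strata: all enrolled infants, attending infants (at
    least one scheduled visit), and completed infants (attended all
    ``n_scheduled_visits`` scheduled visits).  Binary covariates are
    summarised as percentages; numeric ones as median (IQR).
    """
    if covariates is None:
        covariates = cohort.covariate_columns
    attendance = attending_set(cohort)
    enrolled_ids = attendance["infant_id"]
    attending_ids = attendance.loc[attendance["attended_any"], "infant_id"]
    completed_ids = attendance.loc[
        attendance["n_scheduled_visits"] >= n_scheduled_visits, "infant_id"
    ]
    roster = cohort.roster.set_index("infant_id")
    strata = {"enrolled": enrolled_ids, "attending": attending_ids, "completed": completed_ids}

    rows = [{"covariate": "n_infants", **{s: float(len(ids)) for s, ids in strata.items()}, "kind": "count"}]
    for cov in covariates:
        col = roster[cov]
        binary = set(col.dropna().unique()) <= {0, 1, False, True}
        row = {"covariate": cov, "kind": "percent" if binary else "median"}
        for s, ids in strata.items():
            vals = col.loc[ids].dropna()
            if len(vals) == 0:
                row[s] = float("nan")
            elif binary:
                row[s] = float(100.0 * vals.mean())
            else:
                row[s] = float(vals.median())
                row[f"{s}_iqr_low"] = float(vals.quantile(0.25))
                row[f"{s}_iqr_high"] = float(vals.quantile(0.75))
        rows.append(row)
    return pd.DataFrame(rows)
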