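"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the library's code paths: the classifier oracle
scans a day-by-day possession timeline, and the product-limit oracle
enumerates risk sets directly.
"""

from __future__ import annotations

import numpy as np


def brute_classify(schedule, visit_ages, dose_ages) -> dict:
    """Day-scan re-derivation of one infant's trajectory classification.

    Builds the daily cumulative-dose possession series out to the last
    window's end and reads every status off it, independently of the
    implementation's window arithmetic.
    """
    horizon = schedule.last_window_end
    possession = np.zeros(horizon + 1, dtype=int)
    for age in dose_ages:
        if age <= horizon:
            possession[age:] += 1

    windows = []
    for k, d in enumerate(schedule.doses, start=1):
        days = range(d.window_start, d.window_end + 1)
        visited = any(v in days for v in visit_ages)
        received = any(a in days for a in dose_ages)
        # up-to-date: every window j <= k satisfied on its last day
        utd = all(
            possession[schedule.doses[j - 1].window_end] >= j for j in range(1, k + 1)
        )
        unvax = possession[d.window_end] == 0
        windows.append(
            {"visited": visited, "received": received, "up_to_date": utd, "unvaccinated": unvax}
        )

    assessments = []
    prev = None
    for idx, age in enumerate(dose_ages):
        early = age <= schedule.early_cutoff
        spacing = None if prev is None else age - prev
        compressed = spacing is not None and spacing < schedule.min_interval
        assessments.append({"early": early, "spacing": spacing, "compressed": compressed})
        prev = age

    return {
        "windows": windows,
        "assessments": assessments,
        "total_doses": len(dose_ages),
        "cumulative": [int(possession[d.window_end]) for d in schedule.doses],
    }


def km_oracle(durations, observed):
    """Product-limit estimator by direct risk-set enumeration.

    At each distinct event time t: n = subjects with duration >= t (ties
    between events and censorings keep the censored subject in the risk
    set at t), d = events at t, S *= (1 - d/n).  Returns (event_times,
    cumulative probability 1 - S).
    """
    durations = np.asarray(durations, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    times = np.unique(durations[observed])
    surv = 1.0
    out = []
    for t in times:
        n_at_risk = int((durations >= t).sum())
        d = int(((durations == t) & observed).sum())
        surv *= 1.0 - d / n_at_risk
        out.append(1.0 - surv)
    return times, np.asarray(out)
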