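# Methods

## Schedule model

A schedule is an ordered list of doses, each with a target age and a
closed integer-day admissible window, plus a minimum first-dose age, a
minimum inter-dose interval, and an early cutoff. The built-in Zambian
EPI schedule targets 42/70/98 days (6/10/14 weeks) with windows
[41, 69], [70, 97], [98, 127]; window 1 opens one day before the target
to absorb uncertainty in the exact timing of birth and vaccination, so
ages 0–40 are "early". The minimum interval is 28 days (WHO guidance:
minimum 4 weeks between doses, minimum age 6 weeks for dose 1).

Two printed conventions exist for the last window's upper bound (126 vs
127 days); the tabulated outputs we reconcile against use 127, so 127 is
the default and the bound is a constructor argument
(`zambia_epi_schedule(window3_end=126)` selects the other convention).

Ages are whole-day differences from the birth date (day of birth = age
0); all window boundaries are inclusive. Any schedule with the same
structure (e.g. a 2–4–6-month series) can be supplied as YAML.

## Adherence classification

Per infant, doses ordered 1..k with strictly increasing ages are
assessed:

- **early**: administration age ≤ early cutoff;
- **compressed**: spacing from the previous dose < minimum interval
  (undefined for dose 1);
- **window membership**: early / window *k* / between windows / after
  the last window. A dose after all windows (e.g. a lone dose at age
  272 days) stays in the data but contributes to no window statistic.

Window statuses derive from the cumulative dose count at each window's
last day. *Up-to-date* at window *k* means possessing dose *k* by the end
of window *k* **and** having been up-to-date at window *k − 1*: the
metric penalises lateness, never earliness (an early dose counts toward
possession), and once lost is never regained — a later catch-up dose
raises cumulative counts but not up-to-date status. *Unvaccinated* at
window *k* means zero cumulative doses by the window's end.

Only attending infants (≥ 1 scheduled clinic visit) are classified; the
on-study interval runs from enrolment to the last recorded scheduled
visit. Window-table denominators count unique infants with a scheduled
visit inside the window; unscheduled/acute visits never enter
denominators. The per-window unvaccinated count is reported under two
denominators — the window's visitors, and the full attending cohort —
because both are legitimate and materially different bases.

## Rounding

All table percentages use one decimal with ties rounded half away from
zero. This is the only convention under which every printed percentage
cell of the reference coverage tables recomputes exactly from its
numerator and denominator; it is implemented via decimal arithmetic (not
binary-float `round`, which rounds half to even).

## Delay curves

For dose *k*, an infant contributes an event at the administration age,
or censoring at the last scheduled-visit age if the dose was never
observed. Two estimands of F(a) = P(dose by age a):

- **standard**: product-limit (Kaplan–Meier), computed with lifelines;
  censored infants are assumed vaccinated at the same age-specific rate
  as those under observation. Ties between events and censorings at the
  same age follow the standard convention (events first; the censored
  subject is still in that day's risk set).
- **worst-case**: censored infants are assumed never vaccinated during
  the study; the curve is exactly (infants with the dose by a)/N over
  all attending infants. This is a pointwise lower bound on the standard
  curve, as the tests verify.

Delay quantiles use the left-continuous generalised inverse: the
smallest observed age at which the curve reaches q, minus the dose's
target age. Negative delays (vaccination before target) are preserved in
the quantile arithmetic. A quantile the curve never reaches — routine
for the slowest decile of dose 3 under worst-case censoring when a large
minority never receives it — is flagged unattained rather than
extrapolated.

## Relative risks

For a 2×2 table (a, b; c, d) with exposed row (a, b) and outcome-positive
column (a, c): RR = (a/(a+b)) / (c/(c+d)), with the Katz log-scale normal
95% CI and a two-sided Wald p-value on ln RR. A zero cell triggers the
Haldane–Anscombe correction (0.5 added to all four cells, flagged); a
zero margin leaves the estimate undefined and flagged. No multiplicity
correction is applied — the screen is descriptive. Numeric covariates are
dichotomised at their median (above vs at-or-below), recorded in the
output. The demographics table stratifies covariates by enrolled /
attending / completed (attended all six scheduled visits).

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, with these
defaults (all configurable through `SimConfig`):

| parameter | default | meaning |
| --- | --- | --- |
| `enrolment_span` | 300 d | staggered calendar intake (~10 months) |
| `enrolment_age_mean/sd` | 7 / 2 d | enrolment near one week of age |
| `visit_offsets` | 21, 42, 56, 70, 84, 98 d | six scheduled visits at 2–3-week intervals, three coinciding with dose targets |
| `max_visit_age` | 126 d | ceiling on any attended visit (18 weeks) |
| `per_visit_attendance_prob` | 1.0 | chance of attending each planned visit |
| `dropout_hazard` | 0.0 | per-visit-attempt probability of permanent loss |
| `never_attend_prob` | 0.0 | enrollees who never attend (excluded as non-attending) |
| `reschedule_prob` | 0.0 | missed visit re-attempted 14 d later; also governs make-up appointments when a dose was not yet due |
| `hesitancy_fraction` | 0.0 | infants who attend normally but decline every dose |
| `visit_lateness_median` | 0 d | right-skewed (gamma, shape 1.5, discretised) lateness of attended visits |
| `delay_shape`, `delay_median` | 1.5, 2 d | dose-readiness delay added to each dose's earliest eligible age |

Dose *k* is administered at the first attended visit whose age reaches
`max(minimum age, previous dose + 28) + delay_k`. Visit planning mimics
routine EPI practice: after a dose, a follow-up appointment is booked at
the minimum-interval mark unless a planned visit already falls within a
week of it — this is what lets a delayed second dose still lead to a
third dose at 16–18 weeks rather than silently falling off the schedule.

`realworld_config()` is the preset that reproduces the qualitative shape
of a low-resource urban cohort: 24% never attend, 90% per-visit
attendance with a 5% per-visit dropout hazard, 80% rescheduling, a 7%
hesitant core, lateness median 1 d and readiness delay median 0.5 d.
Under it, roughly three-quarters of attenders remain on-study into the
third window, first-dose coverage lands in the low 90s/high 80s, series
completion near 60%, and worst-case median delays grow with dose number
— the minimum interval propagates early slippage forward, which is the
mechanism of interest.

What the generator does **not** emulate: schedule violations by clinic
staff (readiness delays are non-negative, so no early or compressed
doses arise in synthetic data — those classifier paths are exercised by
hand-built fixtures), calendar seasonality, clinic capacity, partial
hesitancy, and any correlation between covariates and outcomes
(covariates are independent by construction, making the risk screen's
null calibration testable). Passing tests on synthetic data therefore
validate the pipeline's arithmetic and the stated cohort mechanisms, not
the realism of any particular community's attendance process.

## Numerical and design choices

- Validation is fail-loud: orphan events, duplicate dose numbers,
  non-increasing dose dates and unparseable dates abort with row-level
  context before any analysis runs.
- Deidentification draws one integer offset per infant, uniform on
  [−3, +3] by default, applied to every date of that infant; since all
  statistics are computed on ages, every analytic output is bit-identical
  before and after (tested end to end).
- Compression is reported at thresholds 28/25/20 days and at both infant
  and event level, since spacing violations can be quoted either way.
- Problem sizes in the examples and acceptance script (1500-infant
  preset cohorts, 5000-infant recovery runs) were chosen to keep
  Monte-Carlo error well inside the tolerances being checked while
  running in seconds.
- Known limitations: no Greenwood confidence bands on the delay curves,
  no adjusted/multivariable risk models, and no likelihood-based fitting
  of the generator to real data — the preset is a qualitative, not
  calibrated, emulation.
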