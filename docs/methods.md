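# Methods

## The problem

Critically ill patients are monitored for blood glucose every few hours
and treated with short-acting insulin boluses, occasional insulin
infusions, and dextrose rescues.  EMR event tables record these events
*separately*: a charted bolus is not linked to the measurement that
prompted it, bolus timestamps are rounded by bedside charting (often to
the hour), and tables contain error-flagged rows, duplicates,
out-of-stay events and impossible values.  `glycurate` implements the
standard descriptive battery for such data — cohort curation, temporal
bolus–measurement matching, time-weighted daily glycaemia, next-day
recurrence risk, dose-given-glucose characterization and a day-1 vs
day-7 test battery — together with a synthetic EMR generator that makes
every stage testable against known ground truth.

## Cohort curation

Inclusion: age ≥ 18 years at ICU admission, length of stay ≥ 24 h, and
at least one glucose measurement charted within the stay.  Exclusion
counts are sequential (missing times, age, length of stay, glucose
availability), so they sum with the included count to the input size.

Event cleaning applies four ordered rules — error flag, exact duplicate
(first occurrence in chart order kept), unknown-stay reference /
outside-stay timestamp, implausible value — and reports per-rule
removals; every input row is retained or removed by exactly one rule,
and cleaning is idempotent.  The plausibility bounds, glucose in
(10, 2000) mg/dL and bolus dose in (0, 100] units, are deliberately
loose and configurable; near-duplicates (same minute, different value)
are retained because no principled fuzziness threshold exists.

Diabetic status comes from case-insensitive substring search of the
subject's notes for configurable keywords (default: "diabetes",
"diabetes mellitus", "insulin dependent").  This reproduces the known
failure mode of keyword flagging — "no history of diabetes" matches
"diabetes" — which the generator can exercise via decoy notes.

## Bolus–measurement matching

Each short-acting bolus is paired with the **most recent** glucose
measurement in the same stay within a window of 60 min before to 10 min
after the bolus charttime (both ends inclusive).  The backward extent
absorbs charting-lag rounding to the hour; the forward extent absorbs
occasional order inversions at data entry.  Exact-timestamp ties break
by highest glucose value (the clinician doses off the alarming reading),
then lowest record id; one measurement may match several boluses (split
doses), making the matching order-independent.  Before matching, insulin
from stays with DKA, beta-blocker overdose or hyperkalaemia diagnoses is
dropped, as is any bolus within 1 h of a calcium-gluconate event — the
window is two-sided, since insulin given for hyperkalaemia can be
charted on either side of the calcium input.  Unmatched boluses are discarded
and reported, along with a matched-vs-unmatched comparison on dose,
diabetic share, nearest-measurement distance and time of stay.

## Daily glycaemia

Stay-days are 24 h blocks anchored at ICU admission (no partial first
day).  The daily average is time-weighted under LOCF: each reading's
weight is the time to the next reading (or day/stay end), with the first
reading extended back to the day start, so bursts of rapid repeat
measurements do not distort the mean; with equally spaced readings it
equals the arithmetic mean.  Event flags use strict thresholds: hypo if
any reading < 80 mg/dL, hyper if any reading > 180 mg/dL (both can fire
on one day); severe thresholds are 50 and 200 mg/dL.  The exclusive
display class gives priority hypo > hyper > eu.

Recurrence is a discrete-time relative risk.  For day pairs (d, d+1),
d = 1…6, stays with measurements on both days contribute a 2×2 count
(event on d × event on d+1); RR_d = P(event d+1 | event d) /
P(event d+1 | no event d).  The headline number pools counts across day
pairs (Mantel–Haenszel-style) before forming the ratio; the unweighted
mean of per-day ratios is reported alongside, since "average hazard
ratio" does not pin down an estimator.  Undefined days are excluded with
a warning.

## Dose-given-glucose analyses

* **Regression**: OLS of bolus dose on {1, glucose, diabetic,
  glucose×diabetic} with heteroskedasticity-robust (HC1 by default,
  HC0–HC3 configurable) standard errors, plus predictions at 200 and
  400 mg/dL for both strata rounded to 2 decimals.  Repeated doses from
  one stay are correlated, so the robust SEs understate within-patient
  dependence; coefficients remain unbiased, which is why conclusions
  rest on predicted doses.  Mixed-effects/GEE modelling is deliberately
  out of scope.
* **Heat map**: column-normalized P(dose bin | glucose bin) over matched
  pairs; default bins 25 mg/dL × 2 units.
* **Bolus probability**: the proportion of glucose measurements followed
  by ≥ 1 short-acting bolus within the *reversed* match window
  (anchored on the measurement), per 25 mg/dL bin and stratum, smoothed
  with a cubic smoothing spline weighted by bin counts.
* **Daily usage**: per stay-day and insulin kind — event counts, total
  units (infusion units are rate × duration clipped to each day) and the
  probability of receiving that kind conditional on still being in the
  ICU that day.
* **Infusion response**: mean glucose by hour in [−12, +12) h around
  each stay's *first* infusion start; per-stay hour means averaged
  across stays, empty cells null.

## Hypothesis tests

Wilcoxon signed-rank compares paired day-1/day-7 time-weighted averages
over each subject's first stay with readings on both days; zero
differences are dropped, the normal approximation is used above 25
informative pairs, and fewer than 5 is refused.  Chi-square (2×2,
day × any-event, no Yates correction by default) tests the change in
hypo/hyper prevalence overall and within diabetic strata; the four
subgroup tests use the Bonferroni-corrected critical p = α/4 = 0.0125 at
α = 0.05.  Low expected cell counts attach a warning; McNemar-style
pairing is available via the battery's options rather than assumed.

## The synthetic EMR generator

Latent glucose per stay is an exactly discretized Ornstein–Uhlenbeck
process on a 5-minute grid: reversion rate 0.2/h, stationary SD
35 mg/dL, around a setpoint of 135 mg/dL (non-diabetic) or 175 mg/dL
(diabetic, 24% of subjects) plus a per-stay N(0, 25) heterogeneity term
— the spread that makes some patients persistently uncontrolled.
Treatment effects ride on a deviation channel with exponential washout
(half-life 2 h): each insulin unit subtracts the stay's sensitivity
(N(15, 5) mg/dL per unit, floored at 2), a dextrose rescue (triggered
below 70 mg/dL) adds 40 mg/dL.

Measurements sample the latent path every 4 h (hourly while an infusion
runs).  A reading above the lowest sliding-scale threshold (default
scale 200→2, 250→4, 300→6, 350→8 units) triggers, with probability 0.9
(10% omissions), a bolus charted 0–60 min later at the scale dose plus
N(0, 0.75) noise, floored at zero and rounded to whole units, with the
charttime rounded to the nearest hour — the charting resolution of real
bedside systems.  The 0–60 min uniform lag is an assumption: the true
distribution of charting lags is unknown.  A reading above 280 mg/dL
starts an infusion (defaults chosen so ~2% of stays receive one) that
relaxes glucose toward 150 mg/dL with a 4 h time constant and ends at
the first sub-trigger reading after 4 h; sliding-scale dosing is
suspended while the drip runs.  Diabetic stays receive basal long-acting
(and occasionally intermediate) insulin that is charted but does not
perturb the latent path, modelling basal maintenance of the setpoint.
Stay scaffolding: LOS ~ gamma (shape 2, mean 96 h, floored at 26 h so
every generated stay meets inclusion), age ~ N(65, 16) clipped to
[18, 95], care units and admission types at realistic frequencies, 10%
of stays being second stays of a returning subject.

The truth sidecar records per-stay parameters, every causal
(measurement, bolus) link with exact pre-rounding timestamps, and — for
`corrupt()` — a ledger naming each injected defect row (error flag,
exact duplicate, out-of-stay copy, implausible-value copy), so cleaning
and matching can be scored exactly.

What the generator does **not** emulate: meals, steroids, circadian
rhythm, measurement error, drifting setpoints, informative measurement
timing, or the heavy-tailed patient mix of a real ICU.  Passing tests
therefore demonstrate correctness of the *pipeline operations* under a
known generative model, not that real-data summaries will match any
particular published cohort; cohort-level numbers from restricted
clinical databases are explicitly out of scope.  One emergent property
is worth noting: with hour-rounded charting and the assumed 0–60 min
lag, about 20% of boluses fall outside the −60/+10 window, giving a
default-regime match rate of ≈0.80 — the same order of loss real
hour-rounded charting produces.

## Numerical and design choices

* OU discretization is the exact AR(1) transition (no Euler error);
  stationary initial condition.
* Matching uses binary search over per-stay sorted measurement times;
  a brute-force all-pairs scan is kept in the test suite as an oracle.
* Day-specific denominators everywhere: a stay contributes to day-d
  summaries only if it has a measurement that day.
* Problem sizes in the checks (500-stay recovery cohorts, 2,000×7
  Markov recurrence, 500-replicate calibration loops) were chosen so
  Monte-Carlo error is a small fraction of each tolerance while the full
  battery runs in well under a minute.
* Degenerate inputs: empty bolus sets match to empty outputs; an
  event-free cohort yields a null recurrence ratio with a warning; a
  constant-glucose or single-stratum design raises an explicit
  degenerate-design error naming the deficient column.

## Known limitations

* Keyword diabetes flagging has the documented false-positive mode on
  negated phrases and false negatives when notes are missing.
* The recurrence ratio is a relative risk over discrete days, not a
  continuous-time hazard; no mortality or outcome modelling.
* Dose regression is descriptive; clustered/autocorrelated errors mean
  its p-values should not be over-read.
* The analysis unit is the ICU stay throughout; hospital-admission or
  patient-level aggregation is the caller's responsibility.
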