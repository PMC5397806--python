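# Methods

## Adjusted PDC

The proportion of days covered is the fraction of observation days on
which dispensed supply was available.  Naive PDC overestimates
adherence in two ways: overlapping supplies from early refills count
days twice, and supply dispensed near the end of follow-up counts days
never observed.  The engine prevents both with a completion-date chain:
fills are processed in dispensing order with `start_i =
max(dispense_day_i, end_(i-1))` and `end_i = start_i + days_supplied_i`
(half-open day intervals; `end_0 = 0`), and the covered set is clipped
to the observation window `[0, W)`.  The chain is deliberately
uncapped: stockpiled supply can be pushed arbitrarily far forward, and
only the window clip bounds its effect.  All arithmetic is integer
days; there is no partial-day logic.

**Hospital days.**  Inpatient medication does not appear in outpatient
dispensation records, so hospitalized days are removed from the PDC
calculation.  The default (`hospital_mode="compress"`) deletes those
days from the timeline before the chain is built, which simultaneously
(a) removes them from the denominator and (b) pauses supply consumption
during the stay — the outpatient supply is plausibly unconsumed while
the hospital medicates the patient.  A stay admitted on day *a* and
discharged on day *d* occupies the inclusive range *a..d*; a fill
recorded during a stay begins contributing on the first post-discharge
day.  The alternative reading, in which supply keeps burning during the
stay and hospital days only leave the denominator, is preserved as
`hospital_mode="denominator_only"`: the chain runs on the observed
clock and the covered set is then projected onto the compressed clock.

**Two measurement methods, one kernel.**  The summary PDC (method A)
and the 102-day interval PDCs (method B) are both read off the same
coverage schedule, so conservation holds exactly: interval covered days
sum to the summary count and the summary PDC is the length-weighted
mean of interval PDCs.  Carryover between intervals needs no extra
rule — the chain was built over the whole window.  The final interval
keeps its true (shorter) length as denominator and is flagged
incomplete; analyses conditioned on "the last completed interval"
(concordance, the last-interval sensitivity variant) use the last
interval flagged complete.  The interval length defaults to 102 days =
three 34-day fills, the usual dispensing quantity in the emulated
setting; it is a parameter.

**Classification.**  Optimal adherence is PDC ≥ 0.80 (inclusive).  The
three-level scheme cuts at ≤ 0.20 and ≥ 0.80; the low boundary is read
as inclusive (≤ 20%), which differs from the alternative reading only
at exactly 0.20.  A window fully swallowed by hospitalization (W = 0)
is a missing-adherence state, never a PDC of any value.

## Cohort selection

A new-user design anchored on an acute coronary syndrome (ACS)
hospitalization: index = earliest eligible ACS discharge; entry
requires age ≥ 30 at index, 1825 days of continuous coverage before
index, an ACS diagnosis (persons with only revascularization episodes
are excluded), no statin dispensation in the 365 days before the index
admission, a first statin fill within 90 days of discharge (inclusive),
and survival with coverage for ≥ 102 days after that fill (death on
exactly day 102 is retained, then dropped by the survival module for
contributing zero at-risk time).  Criteria are applied in a fixed
order — age, prior coverage, ACS-vs-revascularization, washout, fill
window, minimum survival — which affects only the attribution of
exclusions in the flow tally, never final membership.  Because the age
and coverage checks precede the ACS check, persons with only
revascularization episodes are given a provisional index (their
earliest qualifying discharge) so that every exclusion is attributable.
Age is computed as completed years by integer division of days by 365.
Diagnosis and drug code sets are configuration; the synthetic data uses
symbolic codes (MI, UA, REVASC_ONLY, OTHER; "statin").

## Survival analysis

Risk time starts 102 days (one measurement interval) after the first
fill.  Times are measured on the compressed, hospital-free clock, so
that the model's risk intervals and the PDC measurement windows
coincide; at the default hospitalization rates the removed days are
well under 1% of follow-up, so the distinction from calendar time is
numerically immaterial.

Method A enters the summary PDC (binary, three-level or continuous) as
a fixed covariate with duration `W − 102`.  Method B builds
counting-process rows, one per measurement interval intersected with
the at-risk period, and the covariate in force during risk interval *k*
is the adherence of interval *k−1* (**lagged**, the default).  The lag
is a deliberate design decision: each risk interval's covariate is then
a complete, fully observed measurement.  Under concurrent timing the
death interval's covariate is computed on a window truncated by the
death itself — fills cease at death, so the full-interval value is
unobservable in principle, and the short-window classification of the
event row carries almost no information about behaviour (in simulation
a built-in effect of log 0.75 fit back as a hazard ratio of ~1.0 under
concurrent timing).  Concurrent timing remains available
(`timing="concurrent"`) for comparison, and the first at-risk interval
is naturally served by interval 1, which lies entirely before the
origin.

Fitting is by lifelines with the Efron tie correction.
Counting-process rows are fitted as left-truncated segments
(`CoxPHFitter` with an entry column — the Andersen–Gill partial
likelihood; estimates and model-based standard errors are identical to
`CoxTimeVaryingFitter`, which is used instead when robust person-
clustered standard errors are requested).  Crude fits carry the
adherence term only; adjusted fits add a configurable baseline
covariate vector (the generator emits age group, sex, a
revascularization flag and a comorbidity flag; real analyses pass their
own columns).  Non-varying covariates and event-free datasets raise
estimation errors rather than returning degenerate fits.

Diagnostics: Schoenfeld residuals per covariate per event time with a
slope test against event time (lifelines' score test for fixed fits; an
ordinary least-squares slope test on the residual series for
counting-process fits, whose calibration is checked by simulation in
the test suite), log(−log S(t)) curve data per adherence group emitted
for visual assessment rather than auto-judged, and variance inflation
factors (VIF_j = 1/(1−R²_j), flag at 10, infinite under exact
collinearity).  Kaplan-Meier description uses the classical grouped
product-limit estimator for the fixed classification and the extended
(Simon–Makuch-style) estimator for the time-dependent one: each
counting row contributes its person-time to the group matching its
current class, entering the risk set at `start` (left truncation).

The sensitivity suite refits everything: binary, three-level (reference
= low), and continuous adherence for both methods, plus the last
complete interval's class and the first interval's class entered as
fixed covariates — each crude and adjusted, with per-variant errors
recorded rather than aborting.

## Synthetic data generator

The generator emulates the structure of a provincial ACS/statin cohort
over a 15-year study window (5,475 days, day 0 = 1994-01-01 by
convention), with uniform entry over the window.  Per person (all
randomness from a stream keyed by `(seed, person index)`, so bundles
are bit-reproducible):

* demographics near the emulated cohort's margins: age ~ N(64.8, 12.3)
  truncated to [30, 100], 69% male, 58.5% revascularized, 36.7% with a
  comorbidity flag;
* an index admission of 1 + Poisson(7) days (capped at 30), first
  statin fill a capped-geometric 0–90 days after discharge, coverage
  starting 1,825–2,825 days before index — entry is guaranteed by
  construction;
* latent health `H`: a Gaussian random walk at interval resolution
  (baseline SD 1.0, innovation SD 0.25), standing in for the unmeasured
  morbidity that drives both behaviour and death;
* refills: a renewal process — after each 34-day supply exhausts, the
  gap to the next fill is geometric with per-day probability
  `sigmoid(alpha_i + gamma*H_k + trend*calendar_years)`, where
  `alpha_i ~ N(-2.0, 2.0)` is a person-level propensity.  The
  between-person SD of 2.0 produces the strongly bimodal adherence
  distribution characteristic of real refill data (mean summary PDC
  ≈ 0.71, ~53% optimal) rather than a unimodal cloud near the
  threshold;
* death: piecewise-constant hazard per interval, `lambda_k = lambda0 *
  exp(beta*A_{k-1} + theta*H_k)` with `lambda0 = 8e-5`/day (~3% per
  person-year), active from the second interval (the analysis origin),
  sampled by interval-wise inversion;
* hospital stays: Poisson-count 3–14-day episodes *inserted into the
  calendar on top of the behavioural clock*.  Behaviour and death are
  simulated on the hospital-free clock; the stays then stretch the
  calendar when claims are emitted.  Timeline compression in the
  analysis inverts exactly this insertion, which keeps the generator's
  truth table aligned with the measured intervals and reflects the
  modelled reality that stays pause outpatient dispensing and
  consumption.  Terminal in-hospital deaths are not modelled.

Scenario presets set the dependence dials:

| scenario | beta | gamma | other |
|---|---|---|---|
| `null` | 0 | 0 | — |
| `causal` | log 0.75 | 0 | — |
| `survival_bias` | 0 | 0.25 | pre-death decline in H |
| `improving_trend` | 0 | 0 | trend_slope 0.12/yr |

In `survival_bias`, the death time is drawn independently of adherence
and health (requiring beta = theta = 0, enforced), and `H` is stepped
down by 2.0 over the complete measurement interval preceding the death
interval.  The magnitude and extent of the decline and the
health-adherence slope were chosen, by scanning the scenario's
dependence-parameter space, to sit in the regime that defines the
scenario: the refill lapse before death is strong enough to flip the
current-interval classification of most decedents (a clear
repeated-measures signal) while contaminating only ~1 of a typical ~17
measured intervals, so the summary measure stays near null.  Stronger
or longer declines make the *summary* measure spuriously protective as
well, which is a different (and less diagnostic) scenario.

**What the generator does not emulate.**  Accrual is uniform rather
than late-skewed; dosing, switching economics, formularies and provider
behaviour are absent; hospital episodes are independent of health by
default; nobody dies in hospital; primary non-adherence (never filling)
is excluded by construction, as in the emulated design.  Passing tests
therefore demonstrate the *measurement and modelling machinery* —
exact coverage accounting, correct counting-process construction,
calibrated inference, and the direction of survival bias — not fidelity
to any particular health system's marginals.

## Numerical and testing choices

Problem sizes are chosen to keep the full suite fast while leaving
Monte-Carlo error well inside the asserted bands: parameter recovery
uses 50 replicates at n = 5,000 (mean-coefficient tolerance ±0.05 ≈ 5×
the SE of the replicate mean), type-I error uses 200 replicates at
n = 1,000 (band 0.02–0.09 around the nominal 0.05), the survival-bias
divergence uses a single fixed-seed run at n = 9,000 (the scenario's
design point), and the coverage engine is checked exactly — no
tolerance — against a literal day-by-day supply-stack oracle on 1,000
random histories with windows up to 2,000 days.  Hypothesis-based
property tests run derandomized.  Ties in Cox fits use Efron's
approximation throughout; convergence and degeneracy failures surface
as typed errors.

## Known limitations

* The lagged covariate cannot represent genuinely instantaneous
  exposure effects; for drugs with immediate reversible risk (e.g.
  anticoagulant bleeding) concurrent timing with event-day exposure
  status would be the appropriate — and different — design.
* The Schoenfeld slope test for counting-process fits uses an OLS
  approximation rather than the Grambsch–Therneau scaled-residual
  statistic; its simulation-checked calibration is adequate at the
  package's study sizes but conservative refinements exist.
* `denominator_only` hospital handling discards stockpile pausing and
  has no generator counterpart, so it is exercised by unit tests only.
* The generator's survival-bias mechanism is a stylized two-parameter
  decline; real sick-stopper dynamics are heterogeneous in onset and
  depth.
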