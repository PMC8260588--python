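# Methods

## The decision problem

Two treatment schedules for patients starting clozapine are compared per
country (Japan, UK): the current schedule — mandatory blood monitoring, stop
clozapine permanently when the ANC falls below a cutoff — and an HLA-guided
schedule that is identical except that every patient is genotyped for risk
HLA variants before the first dose.  Knowing who carries a risk variant does
not change the monitoring programme; it changes clinician behaviour (e.g.
temporary cessation at an early warning sign), which the model abstracts as
a single **CIAG prevention rate** *r*: the fraction of all CIAG onsets in
the cohort that the guided schedule averts.  The base value is *r* = 0.30,
motivated by a Bayes argument: carriers account for at most ~70–77% of
preventable CIAG (the `epi.max_prevention_rate` bound), and preventing
roughly half of those events yields ~30% overall.

## Cohort engine

* Two states, OnClozapine → OnSubstitute, one-way, absorbing; no death or
  sepsis state and no WBC-triggered exit.  Monthly cycles of 365.25/12 days
  (configurable), horizon 10 years (1–50 supported).
* The onset curve gives *qₜ*, the probability of CIAG in cycle *t*
  conditional on still being on clozapine.  The guided arm uses
  *qₜ*(1 − *r*).  Because the flow is one-way, occupancy is the survival
  product ∏(1 − *qₛ*) and the engine is fully vectorised.
* Rewards for cycle *t* go to the state occupied at the cycle start; the
  transition takes effect at the cycle boundary.  Under this convention the
  expected number of cycles on clozapine at constant hazard equals
  (1 − (1 − q)^N)/q, which is the closed form the tests pin.  An optional
  half-cycle correction (off by default) averages the boundary occupancies
  instead.
* Per-cycle flows: state drug cost × cycle days; monitoring cost for the
  clozapine state only, from a day-resolution test schedule (weekly tests at
  days 7, 14, …, 7·W, biweekly thereafter; a test on day *d* is charged to
  cycle ⌈d/L⌉); the CIAG episode cost charged once, in the transition cycle
  (the episode lasts days, i.e. sub-cycle, so a lump sum is appropriate); the
  HLA typing fee at cycle 0 in the guided arm.  No utility decrement for the
  CIAG episode itself.  Cycle-*t* flows are discounted by
  (1 + rate)^(−t·L/365.25).
* Carriers are not tracked as a separate state: the prevention rate scales
  the cohort-average hazard, because monitoring is identical in both arms.
  Consequently the PPV does not enter the base-case arithmetic.  An opt-in
  hook (`derive_prevention_from_ppv`) recomputes
  *r* = efficacy × (PPV × carrier frequency / cumulative incidence) so that
  one-way variation of the PPV propagates to the ICER; the base case treats
  *r* as primitive.

## Comparative metrics

ΔC/ΔQ is reported only in the north-east quadrant (costlier and more
effective).  Cheaper-and-at-least-as-effective is flagged `dominant`,
costlier-and-at-most-as-effective `dominated` — in both cases no ICER is
calculated.  The south-west quadrant carries the ratio plus an explicit
`southwest` flag, because a bare ratio there inverts the decision logic.
The frontier routine flags strict dominance, then removes extended-dominated
options until sequential ICERs increase; it is property-tested against a
brute-force mixture oracle.

## Sensitivity analyses

* **Tornado**: each of six parameters (prevention rate, PPV, CIAG episode
  cost, clozapine daily cost, substitute daily cost, discount rate) set to
  its low/high bound with all else at base; records sorted by ICER swing,
  ties broken by name.  The prevention-rate default range 20–80% is the
  documented convention; the other default ranges (±25% for costs and PPV,
  0–5% for the discount rate) are package defaults meant to be overridden by
  the user's own table.  The discount-rate entry varies cost and QALY
  discounting together.
* **Threshold search**: bisection on the raw ΔC/ΔQ against a WTP, stopping
  at |ICER − WTP| ≤ £1/QALY or bracket width < 1e−6; a bracket with no sign
  change returns a "no crossing" result, not an exception.
* **Horizon sweep**: full re-run per horizon (3–20 years by default); onset
  curves shorter than the horizon are extended with their last value —
  onset is concentrated in the first six months, so the tail is near-flat.

## Probabilistic sensitivity analysis

Conventional family assignment: beta for probabilities and utilities, gamma
for costs, uniform for bounded plausible ranges; parameters are given
natively or as (mean, 95% CI) moment-matched with sd = width/3.92.
Family/slot mismatches and infeasible moments fail at spec construction, not
at draw time.  Each spec draws from its own sub-stream seeded by
(seed, CRC32(name)), so adding a spec never reorders another's draws;
out-of-range draws are resampled with a capped retry count.  Parameters are
sampled independently (no correlation structure is specified by the source).
The headline "mean ICER" is the ratio of means (mean ΔC / mean ΔQ) — per-
draw ICER means are unstable near ΔQ = 0 — with the per-draw distribution
exported alongside.  Intervals are 0.025–0.975 empirical quantiles with
linear interpolation of order statistics; the CEAC is the fraction of draws
with positive incremental net monetary benefit per WTP grid point.

## Synthetic parameter generator

The analysis needs a parameter table that is only partly printed in the
source text.  The generator reproduces every printed value verbatim
(provenance flag `printed`) and fills the rest with `placeholder` values
chosen once on domain grounds:

| quantity | value | rationale |
|---|---|---|
| cumulative CIAG incidence, cutoff 1500/1000/500 | 1.5% / 0.8% / 0.3% | agranulocytosis proper (~ANC<500) affects ~0.3–0.8% of monitored patients; milder granulocytopenia counted by stricter cutoffs is severalfold more frequent; monotone in cutoff by construction |
| share of onsets in cycles 1–6 | 90% | onset is concentrated within 6 months of initiation |
| onset-curve shape | geometric decay over 240 cycles | smooth early-weighted hazard; 240 cycles covers the 20-year sweep |
| blood-test fee | £7.5 (JPN) / £4.0 (UK) | ~1,000 JPY CBC fee incl. sampling; NHS full-blood-count tariff plus phlebotomy |
| HLA typing fee | £75 (JPN) / £60 (UK) | ~10,000 JPY single-locus HLA typing; two-SNP NHS genotyping |

The fixture PPV is derived by Bayes' theorem from the sensitivity, the
placeholder incidence at the 1500 cutoff, and the carrier frequency, so the
fixture is internally consistent (9.0% JPN, 5.1% UK).

`generate_onset_curve` hits the target cumulative incidence and first-6-
cycle share exactly by constructing the unconditional incidence profile
first (geometric ratio solved by bracketed root finding; or piecewise-flat)
and converting to conditional probabilities through the survival function.
`generate_parameter_set` draws uniformly within template ranges,
re-sorting the per-cutoff incidences so monotonicity always holds.

**What passing tests show — and don't.**  The generator emulates the
*structure* of the study inputs (monotone cutoff-indexed incidence,
early-concentrated onset, printed economics), not their exact supplementary
values.  Green tests therefore demonstrate that the machinery is correct
and that the qualitative findings (guided schedules cost-effective at both
country thresholds; the relaxed-cutoff unscreened schedule dominating the
current one) hold under realistic conditions; they do not certify the
published point estimates, which require transcribing the supplementary
table.  Real parameter tables also carry correlations and asymmetric CIs
that the placeholder distributions do not.

## Microsimulation oracle

Individual patients draw an onset cycle by inverting the survival function
(one uniform per patient, drawn in (0, 1] so a zero hazard can never produce
an onset), then accrue exactly the per-cycle flows defined above via a
closed-form outcome-by-onset-cycle table.  The oracle shares the flow
helpers (monitoring schedule, discounting) but none of the cohort transition
code, so agreement with the engine (within 3 standard errors at 10⁵
patients, across 20 random templates) is an independent check of the
cohort arithmetic.  It does not implement the half-cycle correction.

## Numerical choices and degenerate inputs

* Currency is double-precision GBP throughout; rounding only at report
  boundaries (whole pounds in tables, 1 decimal for the JPY threshold
  conversion, 2 decimals for daily drug costs).
* ΔQ = 0 never divides: such comparisons carry a dominance/equivalence flag.
* Onset curves are truncated/extended to the horizon; probabilities are
  validated into [0, 1] after prevention scaling.
* Quantiles: numpy `linear` method (interpolated order statistics).
* Hardy–Weinberg consistency between a supplied allele frequency and the
  carrier frequency is enforced with tolerance 0.005, matching the ~2
  significant figures of published carrier rates.
* Problem sizes: tests run the PSA at 10²–2×10³ draws and the
  microsimulation at 10⁵ patients; `scripts/acceptance.py` uses 10⁴ PSA
  draws per country.  These sizes keep Monte Carlo error well below the
  asserted tolerances.

## Known limitations

* No patient-level heterogeneity in the cohort engine (that lives in the
  oracle); no adverse effects of substitute antipsychotics; no mortality.
* The 500/1000-cutoff scenarios change only the onset curves; the CIAG
  episode cost is held fixed across cutoffs (both are config slots).
* Monitoring beyond the weekly window is strictly biweekly; monthly
  long-term schedules some registries allow are not modelled.
* Single JPY→GBP conversion; no other currencies.
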