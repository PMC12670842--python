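# Methods

## The model

`demlife` quantifies the burden of dementia in an insured population
aged 65–100 with a three-state Markov illness–death model:

```
non-dementia --DI(x)--> dementia
     |                     |
 non-DM(x)               DM(x)
     v                     v
            dead
```

DI(x) is the age-specific hazard of a first (validated) dementia
diagnosis, non-DM(x) the mortality hazard of the dementia-free, and
DM(x) the mortality hazard of people living with dementia, all per
person-year on single-year-of-age intervals. Hazards are constant within
each interval (exponential survival), which gives closed forms for every
within-interval quantity and exact closed-form test cases.

From radix l_nd(65) = 1 the table evolves as

- l_nd(x+1) = l_nd(x)·e^{−h(x)}, with total exit hazard
  h(x) = DI(x) + non-DM(x);
- decrements d(x) = l_nd(x)·(1−e^{−h(x)})·DI(x)/h(x) (the constant-hazard
  competing-risks split); deaths without dementia are the residual, so
  the accounting identity l_nd(x) = l_nd(x+1) + d(x) + deaths_nd(x)
  holds bit-exactly;
- the dementia state receives new entrants at mid-interval and decays
  with DM(x).

Everything is truncated at age 100: all expectancies are temporary
(age-x-to-100) expectancies, and nobody is exposed beyond the 100th
birthday plus one year.

## Average life expectancy (ALE)

Let e(x) be the remaining years (to 100) of a person in the dementia
state at exact age x — survival under DM alone — and e*(x) the remaining
years alive of a person currently dementia-free at exact age x. Both are
computed by backward recursion; for e*(x) the default ("threestate"
mode) integrates the within-interval onset time in closed form, so years
lived after a later onset count towards e*. The alternative
`nondem_hazard_only` mode evaluates survival under non-DM alone; both
are available because the distinction between "life expectancy of the
non-demented population" readings is genuinely open, and the threestate
reading makes the excess comparison a like-for-like same-age contrast.

The ALE weights each age's expectancy by the model's own decrement
distribution, w(x) = d(x)/Σd(x):

    ALE_dem    = Σ e(x)·w(x)
    ALE_nondem = Σ e*(x)·w(x)
    LYL        = ALE_nondem − ALE_dem
    R          = ALE_dem / (ALE_dem + ALE_nondem)

Normalising the weights (rather than using raw decrement counts, which
sum to the lifetime dementia risk, not 1) is what makes the ALE
interpretable in years and comparable with published magnitudes.
Expectancies enter at the integer age of the onset interval.

Correctness is guarded three ways: constant-hazard closed forms to
1e-12, the exact accounting identity, and a brute-force microsimulation
oracle (piecewise-exponential agents; decrement weights from a
1,000,000-agent pass, per-age expectancies from 25,000-agent cohorts
dropped at each exact age) that must agree within 3 Monte-Carlo SEs on
random hazard grids.

## Old-age smoothing

Observed rates above age 80 fluctuate; before life-table construction
ages 80–100 of each sex × period × transition series are replaced by a
Kannisto logistic hazard μ(x) = a·e^{b(x−80)}/(1+a·e^{b(x−80)}), fitted
by Poisson maximum likelihood on (events, exposure) with analytic
gradients in (log a, log b), objective scaled by total events, L-BFGS-B
from a deterministic start (a = rate at 80 clipped to (1e-6, 0.9),
b = 0.1) with a small deterministic restart grid. Ages below 80 are
never altered; zero-exposure cells below 80 are treated as rate zero
with a warning. The incidence hazard can be smoothed log-linearly
(Gompertz) instead via `di_model="gompertz"`, since incidence has no
logistic-asymptote rationale; the logistic default keeps all three
series on one model.

## Period trends

Counts aggregated by single year of age × period, per sex and
transition, are modelled as NB2 (variance μ + αμ²) with log link, log
person-years offset, covariates (age−c), (age−c)² and a period dummy;
exp(period coefficient) is the rate ratio. The centering age c defaults
to the person-years-weighted mean age of the exposed population
(`compute_centering_age`); published reference values (73.92/75.87 for
incidence and non-dementia mortality, 79.67/82.99 for dementia
mortality, men/women) are accepted as overrides. The dispersion is
estimated by ML from a Poisson-started fit; when the MLE of α sits at
the zero boundary the joint information matrix is singular and the
Poisson limit of NB2 is reported with dispersion 0 — the period RR and
its Wald CI are continuous in that limit.

## Confidence intervals

Age-specific incident-dementia and dementia-death counts are redrawn as
Binomial(n = round(person-years), p = events/n) — person-trials per
person-year being the only size the data offer; a Poisson flag provides
a sensitivity alternative. Each of the (default 1000) replicates refits
the smoothing for the resampled series, rebuilds the life table and
recomputes all ALE quantities; 2.5/97.5 percentile bounds form the CI
and the point estimate always comes from the unresampled data.
Non-dementia deaths are not resampled by default (their exposure
dominates and their counts are an order of magnitude less variable per
rate unit); `resample_set` can include them. Replicates whose smoothing
fit fails are dropped and counted; more than 5% failures abort the
stratum as unstable. Significance between two estimates is judged by CI
non-overlap.

## The synthetic claims generator

No public claims panel of this kind exists, so the generator is a
first-class module producing panels with known ground truth. It
emulates a statutory-insurer design: two period cohorts (baselines 2006
and 2016), each person entering two years before baseline (the wash-out
window) and followed three years after it; sex, month-precision birth
and death dates; quarterly ICD-10 diagnosis claims with an
outpatient/inpatient setting and a verification flag.

Default conditions, chosen once to mirror the emulated study's reported
magnitudes and held fixed thereafter:

| parameter | default | why |
|---|---|---|
| n_per_cohort | 120,000 | reported cohort sizes (~124k / ~116k) |
| frac_female | 0.60 | women's share of person-years |
| entry ages | 65 + Exp(8 y), truncated at 100 | decaying age structure; mean entry ≈ 72–73, giving exposed-mean ages near the reported centering ages |
| DI Gompertz (a at 65, b) | m: 0.007, 0.105; f: 0.008, 0.115 | crude DI ≈ 19/27 per 1000 PY |
| non-DM Gompertz | m: 0.018, 0.085; f: 0.011, 0.100 | crude non-DM ≈ 40/29 per 1000 PY |
| DM Gompertz | m: 0.12, 0.055; f: 0.07, 0.060 | crude DM ≈ 286/212 per 1000 PY |
| period RRs (DI, DM, non-DM) | 0.91, 0.97, 0.93 | mild declines of the observed order |
| record_prob | 0.90 per quarter | imperfect recording without crippling the two-records rule |
| false_pos_rate | 0.002 per person-quarter | rare spurious singles for the validator to reject |
| switch_rate | 0.005 per year | reported insurer-switching of ~0.4–1.7% per 3-year period |

Event times are drawn by inversion sampling of piecewise-constant
(single-year-of-age) hazards with competing risks; one RNG stream per
(seed, period) keeps cohorts independently reproducible. True cases
emit one verified claim per quarter from onset (80% outpatient/verified,
20% inpatient discharge or secondary); false positives are isolated
single unverified outpatient claims (a `paired_false_positives` flag
emits verified pairs to demonstrate the validation rule's failure
mode); a generic non-dementia filler code (I10) adds claim noise.

What the generator does *not* emulate — and what passing tests
therefore cannot show about real claims data: under-recording that
varies by period or age (recording is homogeneous here, so trend RRs
are unattenuated), diagnosis-seeking behaviour changes (e.g. billing
incentives), comorbidity-dependent mortality, duration-in-state
dependence of DM, prevalent-case misclassification beyond the wash-out
mechanism, and any dependence between insurer exit and health.

## Validation rules

A claim is admissible if its dot-stripped code starts with one of
G30, F00, F01, F02, F03, F051; outpatient claims only when flagged
verified; inpatient claims only as discharge or secondary diagnoses. A
person becomes a case when they hold ≥ 2 admissible claims in the
observation period (which subsumes the two-in-one-quarter reading) or a
single admissible claim in the quarter of death. The first valid month
is the middle month of the earliest admissible claim's quarter —
unbiased under uniform within-quarter timing — clamped to the death
month. Cohort entry requires age ≥ 65 at baseline, continuous coverage
through the two-year wash-out, and no valid diagnosis before baseline.
When diagnosis and death share a month the person dies in the dementia
state and contributes 1/24 person-year of dementia exposure, so no rate
cell carries events without exposure. Under-recording is deliberately
not corrected.

## Numerical choices and degenerate inputs

- Ages in completed years from month arithmetic; ages above 100 pool
  into the age-100 cell (logged).
- Expected-time integrals use expm1-based forms with series branches
  below 1e-9 (φ(u) = (1−e^{−u})/u and relatives), so zero hazards are
  exact limits, not special cases.
- Zero total incidence makes the ALE undefined and raises, as do
  all-zero event series passed to the smoother, zero person-years passed
  to `aggregate_rate`, and single-period tables passed to the trend fit.
- The Kannisto optimiser bounds (log a, log b) to keep hazard
  evaluation finite; the flat-data limit drives b → 0 and reproduces the
  pooled rate.

## Problem sizes used in the shipped tests and script

The test suite simulates cohorts of 6,000–100,000 persons (20 seeds of
100,000 × 2 cohorts for trend recovery), runs the microsimulation oracle
with one million weight agents per grid on five grids, and the CI
calibration study with 200 datasets × 200 replications. The acceptance
script runs the full study at the default 120,000 persons per cohort
with 1,000 bootstrap replications. These sizes reproduce every stated
tolerance with sampling error to spare.

## Known limitations

- The stationarity, synthetic-cohort and Markov (no duration-in-state)
  assumptions of the illness–death model are inherited, not relaxed.
- No recovery transition and no dementia subtypes/severity.
- Percentile bootstrap only; no BCa or delta-method intervals.
- The binomial-n = rounded-person-years convention is one defensible
  reading of "bootstrap assuming a binomial distribution"; the Poisson
  flag exists precisely because the convention is not unique.
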