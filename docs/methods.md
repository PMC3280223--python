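# Methods

## Model and assumptions

The analysis treats road-traffic deaths over a one-year window as a closed
population of unknown size `n`, observed by two imperfect enumerations: a
hospital trauma registry (size `d1`) and police accident reports (`d2`),
with `m` deaths linked to both. Under independent captures, the
continuity-corrected two-source estimator

    n̂ = (d1+1)(d2+1)/(m+1) − 1,
    var(n̂) = (d1+1)(d2+1)(d1−m)(d2−m) / [(m+1)²(m+2)]

is nearly unbiased even at small overlap and is defined at `m = 0`; the
uncorrected ratio `d1·d2/m` is not. When one source is a subset of the other
(`m = d1` or `m = d2`) the variance is exactly zero and the interval
collapses to the point estimate — the correct degenerate behaviour for a
fully nested pair. 95% intervals are Wald-form with `z` fixed at 1.96.

Key assumptions, and how the package addresses their failure modes:

* **Perfect linkage.** False matches inflate `m` and deflate `n̂`; missed
  matches do the opposite. The linkage stage is deterministic and auditable,
  and the strict-matching sensitivity analysis bounds the effect of the
  most consequential linkage choice (see below).
* **Independence of sources.** Violated whenever capture probabilities share
  covariate structure. Stratified estimation (below) is the mitigation.
* **Closure.** Taken as given for a one-year window; not modelled.

## Record linkage

A hospital/police record pair is compared on five criteria: gender equality,
age within 5 years (inclusive), injury mechanism equality, location-code
equality, and absolute event-time difference within 3 hours (inclusive, on
the absolute timestamp axis, so windows cross midnight naturally). A
criterion with a missing value on either side is *unevaluable*; a pair is a
candidate when no criterion disagrees and at most one is unevaluable. The
strict sensitivity variant allows zero unevaluable criteria and requires age
to agree.

Candidates are resolved to a one-to-one matching greedily in order of
increasing discrepancy — `|Δage|/5 + |Δtime|/3h` over evaluable numeric
criteria plus 1 per unevaluable criterion — with record ids breaking ties.
Greedy resolution is not globally optimal, but it is deterministic,
explainable row by row, and exact whenever true pairs dominate their
alternatives, which holds by construction on clean synthetic data (the
test-suite asserts precision = recall = 1 there).

Two representational choices matter: location match is exact equality of
pre-coded location identifiers (free-text village/landmark adjudication is
not reproducible in software and must happen upstream), and a record with a
date but no time of day is stored date-only and treated as time-missing in
matching rather than being assigned a fictitious midnight time.

## Stratified estimation and source-dependence testing

Capture heterogeneity that is shared between sources biases the pooled
estimator. The package stratifies on four factors — gender (male / female /
missing), road-user type (with other/missing pooled), victims per incident
(1–2 vs ≥3) and vehicles per incident (0–1 vs ≥2) — applies the estimator
within each stratum and sums the *unrounded* stratum estimates; rounding
(half away from zero) happens only at report time. Summing rounded stratum
estimates would differ — the vehicles stratification gives 284.88 + 111.50 =
396.38 → 396, not 285 + 112 = 397 — so the order of operations is load-bearing
and tested. A matched pair whose two records imply different strata takes
the police-side stratum (the police source had complete data in the
motivating study); conflicts are logged. Binning is total: missing values
form their own stratum (gender), join an other/missing stratum (road user),
or a flagged missing stratum (count factors).

Pearson chi-squared tests (no continuity correction) on the stratum × source
table of captured records flag factors along which the sources' samples
differ; all-zero strata are dropped and expected cells below 5 raise a
warning rather than switching to an exact test.

## Confidence intervals for stratified estimates

The Wald interval is unreliable in strata with overlap near zero (its lower
bound can fall below the observed count). Stratified estimates therefore
carry a parametric-bootstrap interval: for each stratum, set
`N* = max(round(n̂), d1+d2−m)`, `p1 = d1/N*`, `p2 = d2/N*`; per replicate,
capture `N*` individuals independently per source (a multinomial draw over
the four capture cells), recompute the Chapman estimate from the simulated
counts, and sum across strata. The reported interval is the point estimate
± 1.96 × the replicate standard deviation, per stratum and for the total.

Raw 2.5/97.5 bootstrap percentiles are deliberately not used: the replicate
distribution of the estimator is right-skewed through its `1/(m*+1)` factor,
so a percentile interval is shifted upward relative to the estimator's
sampling variability even at moderate overlap (for a stratum like
(d1=73, d2=124, m=31) the percentile interval sits ~8–14 deaths above the
analytic Wald interval, while the SD-based interval agrees with it to within
~3). The SD-based interval inherits the bootstrap's variance estimate, stays
centred on the estimate, degenerates exactly to the point for nested strata
(constant replicates), and matches the analytic interval wherever the latter
is trustworthy. Replicates with zero simulated overlap use the estimator
as-is; 10,000 replicates is the default, and results are deterministic for
a fixed seed.

## Incidence

`incidence = 1000 · n̂ / population person-years`, applied to the estimate
and both CI bounds, reported to 3 decimals. The default denominator,
1,898,000 person-years, is the package's derived reconstruction of the
motivating study's census denominator: that study prints estimate–incidence
pairs but not the denominator itself; the feasible interval consistent with
all seven printed pairs is (1,897,284; 1,900,419) and the default is a round
value inside it. Any analysis of other data must supply its own denominator.

## Synthetic dual-registry generator

The generator draws `n_true` latent deaths with independent covariates
(gender, age, road-user type, victims and vehicles per incident, event time
uniform over one year, location code from a finite alphabet), captures each
death independently per source with probability
`logistic(base + Σ effects)` on the log-odds scale, records ground-truth
links, then corrupts the registries (per-field missingness, age and time
jitter). Stage-level seeds are derived from one master seed so that, e.g.,
changing the corruption model does not change the latent population.

Defaults are the study-like conditions: 380 deaths in ~1.9 million
person-years; police effects +0.9 (male), +0.35 (pedestrian, driver), −0.6
(passenger), −0.3 (bicyclist), +0.5 (≥2 vehicles); a gender-only hospital
effect of +0.6 (male). Baseline log-odds (−1.538 hospital, −1.337 police)
were solved against the analytic covariate distribution so expected captures
are 97 and 143. These choices make the police sample more male, more
pedestrian/driver and more multi-vehicle than the hospital sample — the
documented contrast between such sources — while the shared gender effect
induces positive source dependence: the pooled estimator is biased low by
roughly 12–15 deaths in expectation while the gender-stratified total is
nearly unbiased, which is exactly the situation stratification exists to
correct, and is asserted by the test-suite. Hospital missingness defaults to
the study profile (age 47%, time 7%, location 4%); police fields are
complete. Jitter defaults: ±2 years age, ±30 minutes time.

What the generator does **not** emulate: realistic age or time-of-day
distributions (uniform by default, configurable), spatial structure in
locations, multi-victim record expansion (each record is one person;
victims-per-incident is an attribute), migration in or out of the
population, and non-fatal injuries. Passing tests on synthetic data
therefore validate the estimation and linkage machinery under the stated
capture model, not the realism of any particular covariate distribution.

## Published-counts fixture

Because the original registries are unavailable, the package constructs a
registry pair carrying the study's published per-stratum marginals exactly
(36 matched, 107 police-only, 61 hospital-only records, with each factor's
stratum counts and the hospital missingness profile, including the
multi-missing overlap: two records missing age+time, one missing
age+time+location, all confined to the unmatched set). Unique location codes
per event and 9-hour event spacing make the planted pairs the only possible
linkage candidates, so the pipeline's output on this fixture is an exact,
executable regression test of linkage + stratification + estimation
jointly: it reproduces every published estimate cell (380 pooled with CI
298–463; stratified totals 364, 370, 366, 396; all stratum estimates) and
every printed incidence. On this fixture the strict-matching sensitivity
yields m=14 and incidence 0.495/1000 py — within the 0.448–0.592 range the
motivating study reported for its age-required matching variant.

## Numerical choices and problem sizes

* Rounding of reported counts: half away from zero; incidence to 3 decimals.
* `z = 1.96` fixed; no re-derivation from the normal quantile function.
* Analytic lower CI bounds are not truncated at the observed count.
* Chapman is evaluated at `m = 0` (no special-casing); invalid counts
  (`m > min(d1, d2)`, negatives) are rejected at construction.
* Validation experiment sizes: estimator calibration uses 1,000 replicates
  of (n=1000, p1=0.3, p2=0.4); the heterogeneity-correction contrast uses
  500 replicates at the default configuration; bootstrap CIs use 10,000
  replicates. These sizes give Monte-Carlo error comfortably below the
  effects being measured.

## Known limitations

* Greedy one-to-one linkage has no optimality guarantee under heavy noise;
  a probabilistic (Fellegi–Sunter) weighting is out of scope.
* Only two sources are supported; log-linear models for three or more
  captures, and Bayesian variants, are out of scope.
* The heterogeneity tests compare marginal source distributions; they do not
  model conditional recapture rates.
* Stratification corrects only dependence carried by the stratifying factor;
  residual dependence through unmodelled covariates remains.
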