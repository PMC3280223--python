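# recapture

Two-source capture–recapture estimation of road-traffic mortality from a
pair of incomplete surveillance registries — a hospital trauma registry and
police accident reports — linked by fuzzy record matching.

In settings without vital registration, neither a hospital file nor a police
file observes all road-traffic deaths. Treating the two registries as two
independent "captures" of a closed population lets the overlap between them
estimate how many deaths *neither* source recorded. This package implements
that analysis end to end for epidemiologists and injury-surveillance teams:
record linkage, estimation with confidence intervals, stratification to
control source dependence, incidence conversion, and a synthetic
dual-registry generator for validating every step against a known truth.

## The statistic

With `d1` deaths in the hospital registry, `d2` in the police file and `m`
linked to both, the continuity-corrected (Chapman) estimator of the total is

    n̂ = (d1 + 1)(d2 + 1) / (m + 1) − 1

    var(n̂) = (d1 + 1)(d2 + 1)(d1 − m)(d2 − m) / [(m + 1)² (m + 2)]

with 95% CI `n̂ ± 1.96 √var(n̂)`. The estimator assumes a closed population,
perfect linkage and independent sources. Because the two registries are
*not* independent samples — capture probabilities share covariate structure
(gender, road-user type, incident size) — the package also applies the
estimator within covariate strata and sums the unrounded stratum estimates,
with a parametric-bootstrap confidence interval for the stratified total.
Chi-squared tests on the stratum × source table flag the factors along which
the sources differ. Estimates convert to incidence as deaths per 1000
person-years given a census denominator.

Record linkage follows fuzzy criteria suited to registries without names or
civil IDs: gender, age within 5 years, injury mechanism, location code, and
time within 3 hours must agree, with at most one criterion unevaluable due
to missing data. A strict variant (age required to match, no missing
criteria allowed) quantifies the sensitivity of the estimate to the
one-missing-allowed rule.

## Worked example

The package ships a deterministic registry pair carrying the published
per-stratum record counts of the motivating dual-registry study (97 hospital
and 143 police records). Running the full pipeline on it:

```bash
recapture reproduce-table1 --mc-reps 10000 --seed 0
```

prints (abridged):

```
Stratified by            Matches Unm.police Unm.hospital     Estimate (95% CI)        Incidence (95% CI)
total                         36        107           61       380 (298-463)    0.200 (0.157-0.244)
gender
  male                        31         93           42       288 (221-356)
  female                       5         12           16        65 (22-108)
  missing                      0          2            3        11 (3-19)
  total                       36        107           61       364 (283-445)    0.192 (0.149-0.234)
...
vehicles_per_incident
  total                       36        107           61       396 (274-519)    0.209 (0.144-0.273)
Sensitivity (strict age-required matching): relaxed m=36 est=380 inc=0.200; strict m=14 est=940 inc=0.495
Raw-source incidence: police 0.075, hospital 0.051 per 1000 person-years
```

Reading: the two sources together observed 204 distinct deaths, yet the
overlap of only 36 implies roughly 380 deaths occurred — about 2.7× the
hospital count and 4× what either source's incidence alone would suggest
(0.051 and 0.075 vs 0.200 per 1000 person-years). Stratified totals
(364–396) bracket the pooled estimate; requiring age to match inflates the
estimate 2.5-fold because nearly half the hospital's victims are unidentified
(age missing), showing why the one-missing-allowed rule matters.

The numbered drivers under `analysis/` run the same steps as a narrative:
`01_build_registries.py` (inputs), `02_link_records.py` (linkage),
`03_estimate_deaths.py` (the table above), `04_validate_estimator.py`
(estimator calibration and the pooled-vs-stratified bias contrast on
synthetic data), `05_sensitivity_strict_matching.py`. Outputs land in
`results/`.

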