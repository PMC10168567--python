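# Methods

This note records the statistical conventions, numerical choices and design
decisions behind the package, in the spirit of a model-documentation page:
what is estimated, under which assumptions, and what the synthetic-data tests
do and do not demonstrate.

## The classification rule

The EPIPHANY Index is a ternary decision tree over six predictors measured
immediately before the radiological confirmation of the PE: adapted-Hestia
status, presentation type (suspected / unsuspected symptomatic / unsuspected
asymptomatic), RECIST response grouped as {PD, UK, NE} vs {CR, PR, SD, NED},
previous primary-tumor resection, SpO2 and ECOG-PS.  The tree and the
adapted Hestia checklist are configuration **data** (`models/*.yaml`), not
code: the interpreter validates a tree structurally (single root, acyclic,
no dangling branches) and then proves exhaustiveness and determinism by
enumerating a discretized lattice over the split variables (840 points,
with SpO2/ECOG probes bracketing every cutpoint in use).

**Open transcription issue.** The index is published as a flowchart figure,
and the accompanying text lists the variables but not the internal node
order or the SpO2/ECOG cutpoints.  The shipped default tree is therefore a
*reconstruction*: it is consistent with the published variable list, the
printed RECIST grouping, and two structural guarantees (an episode meeting
any adapted Hestia criterion is never low-risk; switching a Hestia flag on
never lowers the category — both verified by enumeration, and the
monotonicity audit reports rather than hides violations for user-supplied
trees).  The SpO2 cutpoint of 93% and the ECOG-PS ≤2 cutpoint inside the
Hestia-positive incidental branch are reconstruction choices.  Users holding
the original figure can transcribe it into the same YAML format and pass it
with `--tree`; every analysis downstream is unchanged.

Threshold inequalities are applied exactly as printed (SBP exactly 100 or
SpO2 exactly 90 trigger nothing).  The two bleeding-related Hestia items are
clinical-judgment flags taken from the input, never computed.

Comparator point scores are the same kind of data.  sPESI and PESI ship
enabled, transcribed from their original publications with 30-day mortality
per class; items that need covariates outside the cohort schema (PESI's
comorbidity, temperature and mental-status items) carry an explicit
missing-data policy — `error` makes the score unevaluable (the pipeline
skips it with a named warning), `assume_false` (sPESI's comorbidity item)
treats the absent column as negative.  RIETE, Geneva and the Spanish score
are disabled stubs awaiting user-supplied coefficients.

## Bayesian binomial estimation

Per-stratum event probabilities θ use the Jeffreys Beta(½, ½) prior: k
events in n episodes give Beta(k+½, n−k+½).  The report tables print the
**raw proportion k/n** as the point estimate and also emit the posterior
mean and mode; this resolves an inconsistency in the source report, whose
stratum table prints raw proportions while its summary quotes posterior
means (5/232 → 2.2% raw, 2.4% mean).

Two 95% interval conventions are computed everywhere:

- **HDI** — the narrowest interval with the nominal mass, found by
  minimizing `q(p + mass) − q(p)` over the lower-tail probability p with
  bounded scalar optimization (tolerance 1e-10); boundary-mode posteriors
  (a ≤ 1 or b ≤ 1) get a one-sided interval from the boundary.  Verified
  against a dense grid-search oracle to 1e-6.
- **central** — equal-tailed quantiles.

The source analysis estimated its intervals by MCMC, and its printed "HDI"
bounds track the *equal-tailed* quantiles (for 12/229 the printed 2.9–8.7 is
the equal-tailed interval to two decimals, while the exact HDI is 2.7–8.4).
The reproduction script therefore reports equal-tailed bounds; for the
near-symmetric posteriors (both shapes large, e.g. 107/900) the two
conventions coincide within rounding.  Residual 0.06-pp discrepancies on two
bounds are consistent with finite-chain Monte-Carlo jitter in the published
values.

Exceedance probabilities P(θ_A > θ_B) for independent posteriors are
evaluated as ∫ f_A(x) F_B(x) dx by adaptive quadrature (absolute tolerance
1e-9), with a seeded Monte-Carlo path that must agree within sampling error.
Exact quadrature gives 96.2% for the intermediate-vs-low comparison where
the source prints 95.8% — again within MCMC noise of a 10k-draw chain.

The assurance sample-size helper inverts "95% interval width < w attained
with probability ≥ 90% at θ" by seeded simulation over candidate stratum
sizes (≥10,000 replicates, widths cached per distinct simulated k, bisection
after doubling).  Because "width" is ambiguous in such rules, both the
full-width and half-width readings are computed and reported side by side;
under the full-width reading with θ = 0.02 and w = 0.02 a stratum of ~300 is
far from sufficient, so neither reading is asserted to reproduce the
original 900-participant calculation.

Report rounding is one decimal in percent, half away from zero.

## Diagnostic accuracy

Proportion intervals use the Wilson score method; likelihood-ratio intervals
use the log method (Simel).  Metrics with empty denominators are returned as
flagged undefined values, not exceptions.  The dichotomized index means
"high vs {low, intermediate}".  AUCs are Mann-Whitney statistics with the
standard ½-weight for ties (midranks); the paired DeLong comparison builds
the covariance from per-subject structural components and refers the AUC
difference to a normal z.  The published NPV 97.8%/NLR 0.16 for the
dichotomized index cannot be reconstructed from the published per-stratum
counts (which give 96.3%/0.28); since the underlying 2×2 is not printed,
those two numbers are not reproduction targets, while the Hestia counts give
97.7%/0.17 as published.

Logistic regression for the six predictors is fit by Newton scoring (IRLS),
tolerance 1e-8, at most 50 iterations; constant columns are rejected up
front and (quasi-)complete separation is flagged from runaway
coefficients/standard errors.

## Time-to-event analyses

Kaplan-Meier with Greenwood variance; the median is the first time the curve
reaches 0.5 and its interval comes from inverting the log(−log) confidence
band (the Brookmeyer-Crowley construction); an all-censored sample yields a
flagged undefined median.  Ties between events and censorings at the same
time follow the events-first convention.  Cumulative incidence of bleeding
and rethrombosis with death as the competing event uses the Aalen-Johansen
estimator; with a single cause it reduces exactly to 1 − KM.

**Gray's test** (two groups, unit weight, i.e. ρ = 0) compares
subdistribution-hazard increments using Gray's modified risk sets
R_k(t) = Y_k(t)(1 − F̂_k(t−))/Ŝ_k(t−), which keep subjects who failed from
the competing cause represented in the risk set.  The variance attached to
the score is the hypergeometric (log-rank-type) form evaluated on those
modified risk sets; it coincides with Gray's estimator in the absence of
censoring and was validated two ways: against the R `cmprsk` reference
implementation (statistics within a few percent, p-values typically within
0.01; one fixture is frozen as a cross-check test) and against a
label-permutation oracle of the same statistic (agreement within 0.03 at
n = 30, type-I error within 0.05 ± 0.03 at n = 200).  Only the two-group,
single-cause, ρ = 0 case is implemented — the case the validation analysis
uses.

## Synthetic cohort generator

The generator emulates the *statistical* structure of the validation cohort,
not its clinical correlations.  Defaults are the study conditions: 900
episodes split 232/229/439 across strata; per-stratum 15-day complication
probabilities 5/232, 12/229, 90/439; 30-day mortality 1/232, 7/229, 57/439;
OS medians 16.5/14.4/4.4 months; 6-month bleeding incidence 6.2% (low or
moderate) vs 12.7% (high) and rethrombosis 2.9% vs 7.0% with death
competing; outpatient fractions 273/461 (low/moderate, the published split
between low and intermediate being unavailable, the same fraction is used
for both) and 78/439 (high); prior anticoagulation 110/900.

Sampling is stratum-first: a stratum, then a tree leaf of that category,
then feature values satisfying the leaf's predicate path, with free
covariates from the published baseline marginals.  This yields the
round-trip guarantee — classification returns the sampled stratum for every
episode — which is asserted at generation time and re-checked in tests.

Model choices:

- **Overall survival** is a two-piece model: death within 30 days with the
  configured stratum probability (uniform on (0, 30/30.44] months), else
  30 days plus an exponential whose rate is solved so the stratum survival
  median equals the configured value (so the KM median is exact by
  construction).  A single exponential cannot honor the configured 30-day
  mortality and the OS median simultaneously (an exponential with median
  16.5 months implies 4.1% 30-day mortality against the configured 0.43%),
  which is why the two-piece form is used.  One month = 30.44 days
  throughout.
- **Bleeding and rethrombosis** are separate competing-risks processes
  (each vs death), constant cause-specific hazards, with the event hazard
  calibrated by monotone root finding (tolerance 1e-10) so the 6-month
  Aalen-Johansen incidence hits the configured target given the stratum
  death hazard ln 2 / median.  They are not coupled to the OS field; the
  analyses treat them separately, as the validation did.
- **Complication day** is a truncated geometric on 0..15 calibrated so the
  median is 4 days (only the median and range are published).
- **Vitals** are truncated normals confined to the side of each Hestia
  threshold implied by the sampled criterion set; an episode required to be
  Hestia-positive has at least one criterion forced on.

What passing tests show — and what they do not: parameter recovery at
n = 100,000 (complication rates within ±0.3 pp, KM medians within ±0.3
months, 6-month incidences within ±0.5 pp) demonstrates that the estimators
and the generator are mutually consistent at the study's parameter values.
It does not validate the clinical rule on real patients: the generator draws
free covariates independently, contains no center effects, calendar-time
accrual, missing-data mechanism, or outcome correlations beyond those
explicitly configured (in particular, the 15-day complication indicator and
the 30-day death indicator are sampled marginally, not jointly).

## Problem sizes in routine runs

The shipped tests use the study-size cohort (n = 900) for pipeline checks,
n = 100,000 for parameter recovery, 10,000 label permutations and 2,000
bootstrap resamples for the oracle comparisons, and 500 replicates for the
Gray null-calibration sweep; these sizes keep every Monte-Carlo tolerance at
3 standard errors or better.

## Known limitations

- The default tree is a reconstruction (above); per-leaf outputs are
  reported so a verbatim transcription can be compared leaf by leaf.
- Gray's test variance is the log-rank-type form on subdistribution risk
  sets, not Gray's full estimator; the difference was measured as small
  (validated against `cmprsk` and permutation) but is not zero under heavy
  censoring.
- No hierarchical pooling across strata, no Cox or Fine-Gray regression,
  no optimal-threshold or decision-curve analysis — none are part of the
  validation design this package implements.
- `predicted_vs_observed` compares observed deaths with class-level
  predicted probabilities; it is a calibration-in-the-large check, not a
  recalibration.
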