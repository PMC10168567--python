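# epiphany

Risk stratification and validation analytics for **cancer-associated pulmonary
embolism (PE)**.

PE found in patients with active cancer spans a wide severity spectrum, from
incidental findings on staging CT to hemodynamically unstable events.  The
**EPIPHANY Index** is a decision-tree rule that classifies each episode as
low, intermediate or high risk of *serious complications within 15 days* of
the radiological diagnosis, combining the adapted **Hestia criteria**
(hypotension SBP <100 mmHg, SpO2 <90%, RR ≥30/min, HR ≥110/min, sudden or
progressive dyspnea, other admission criteria, clinically relevant bleeding,
high bleeding risk, platelets <50,000/mm³) with oncologic covariates
(RECIST response grouped {PD, UK, NE} vs {CR, PR, SD, NED}, primary-tumor
resection, presentation type, SpO2, ECOG-PS).

This package implements the rule and the statistical machinery used to
validate such a rule on a prospective cohort:

- **`cohort_io`** — episode-level data model, CSV schema, validation,
  endpoint derivation (events before diagnosis are predictors, events on days
  0–15 after diagnosis are outcomes).
- **`risk_models`** — adapted Hestia assessment, the decision tree (shipped
  as reviewable YAML data, not code), and point-score comparators (sPESI and
  PESI transcribed from their original publications; RIETE/Geneva/Spanish as
  user-completable stubs), plus predicted-vs-observed 30-day mortality.
- **`bayes_binomial`** — the Bayesian alternative to the binomial test: the
  per-stratum complication probability θ gets a Jeffreys Beta(½, ½) prior, so
  k events in n episodes give the posterior Beta(k+½, n−k+½).  Highest-density
  and equal-tailed 95% credible intervals, posterior exceedance probabilities
  P(θ_A > θ_B) by quadrature or Monte Carlo, and assurance-style sample-size
  inversion for a target interval width.
- **`diagnostics`** — sensitivity/specificity/PPV/NPV (Wilson intervals),
  likelihood ratios (log-method intervals), paired AUC comparison by the
  DeLong test, and multivariable logistic regression over the index's six
  predictors with separation diagnostics.
- **`time_to_event`** — Kaplan-Meier (Greenwood variance, median with
  Brookmeyer-Crowley-style interval), log-rank, the Aalen-Johansen
  cumulative-incidence estimator for bleeding/rethrombosis with death as a
  competing risk, and Gray's two-sample test of cumulative incidence.
- **`synthetic_cohort`** — a generator that emulates the validation study's
  statistical structure (strata 232/229/439 of 900, per-stratum complication
  and mortality probabilities, OS medians 16.5/14.4/4.4 months, 6-month
  bleeding/rethrombosis incidences 6.2%/12.7% and 2.9%/7.0% with competing
  death), with a round-trip guarantee: every generated episode classifies
  back to its sampled stratum.
- **`pipeline` / `cli`** — the full validation run and a `validate` /
  `simulate` command-line interface.

## Worked example

```python
>>> from epiphany import jeffreys_posterior, hdi, central_interval, prob_greater
>>> low = jeffreys_posterior(5, 232)      # 5 complications in 232 low-risk episodes
>>> round(100 * low.raw, 1), round(100 * low.mean, 1)
(2.2, 2.4)
>>> iv = central_interval(low)            # equal-tailed 95% interval
>>> (round(100 * iv.lower, 1), round(100 * iv.upper, 1))
(0.8, 4.7)
>>> inter = jeffreys_posterior(12, 229)
>>> round(100 * prob_greater(inter, low), 1)   # P(theta_int > theta_low)
96.2
```

The raw proportion in the low-risk stratum is 2.2% (posterior mean 2.4%),
with 95% of the posterior mass between roughly 0.8% and 4.7%; the posterior
probability that the intermediate-risk complication rate exceeds the low-risk
rate is about 96%.

Simulate a cohort and run the whole validation:

```sh
epiphany simulate --out cohort.csv --seed 7
epiphany validate --input cohort.csv --out report/ --seed 7
```

`report/` then contains the stratum table (counts, raw %, posterior
mean/mode, both 95% intervals for complications and 30-day mortality, for the
index and for the Hestia rule), posterior exceedance probabilities, the
model-comparison metrics with pairwise DeLong tests, KM curves and medians by
stratum, Aalen-Johansen bleeding/rethrombosis incidences with Gray's tests,
the logistic odds-ratio table, a per-leaf tree reconstruction, the
prior-anticoagulation sensitivity run, the outpatient subgroup, and a run
log.

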