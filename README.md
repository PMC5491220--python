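# nabassay

Quantitative scoring and population analysis of **natural-antibody (nAb)
assays** in wildlife plasma. The package implements the two plate-reader
assays used to measure germline-encoded IgM immunity in desert bighorn
sheep — and the statistics that compare populations — as a tested,
reproducible pipeline:

* **Bacterial killing assay (BKA).** Diluted plasma is incubated with
  bacteria and OD600 is read at inoculation and then hourly from 5 h to
  14 h. Growth curves show a lag, a linear rise, and a plateau. Killing
  capacity is summarised as the *time to threshold*: the OLS line fitted
  to the linear phase is inverted at OD600 = 0.3,

  t̂ = (0.3 − â) / b̂,

  where â, b̂ are the fitted intercept and slope. Samples with no
  detectable growth over the 14 h incubation are right-censored at 15 h.
  Times are natural-log transformed, and each sample is classified
  against the mean crossing time of four plasma-free controls:
  *no killing* (t̂ ≤ control mean), *intermediate killing* (t̂ greater),
  *absolute killing* (no growth).

* **nAb / IgM ELISA.** A450 readings on 96-well plates coated with
  bacterial cell-envelope protein: replicate aggregation (mean, SD, SE),
  exact Mann–Whitney comparisons against background wells at the
  Bonferroni-corrected level α < 0.017, competition specificity
  (fractional signal loss after antigen pre-incubation,
  1 − competed/uncompeted), and total IgM via a four-parameter-logistic
  standard curve.

* **Population statistics.** Linear mixed models of the log response,
  ln y = β₀ + β₁·population + u_sex + ε with a random intercept per sex
  (REML, Wald or LRT p-values), individual-level cross-assay regressions
  with r² and 95% confidence bands, and killing-class summaries.

* **Synthetic cohorts.** A generator with known ground truth emulates the
  study design — two populations (43 + 50 animals) differing in latent
  nAb, a sex random effect, killing strength increasing with nAb (complete
  suppression emerges when the growth delay exceeds the incubation
  horizon), duplicate ELISA wells at 10% CV, ~93% competition reduction,
  and a total-IgM variable sharing 25% of its variance with reactive nAb —
  so every downstream stage is testable without any external data.

## Worked example

```python
from nabassay import (AssayConfig, CurveRole, DEFAULT_TIME_GRID,
                      GrowthModelParams, classify_killing, control_baseline,
                      score_bka, simulate_growth_curve)

config = AssayConfig()
control = simulate_growth_curve(GrowthModelParams(lag_h=3.0), DEFAULT_TIME_GRID,
                                sample_id="control", role=CurveRole.CONTROL)
delayed = simulate_growth_curve(GrowthModelParams(lag_h=6.0), DEFAULT_TIME_GRID,
                                sample_id="delayed")
baseline = control_baseline([control] * 4, config)
result = score_bka(delayed, config)
print(baseline, result.t_threshold, classify_killing(result, baseline).value)
```

prints `5.50 8.50 intermediate_killing`: the plasma-free controls cross
OD 0.3 at 5.5 h, the plasma sample delays the crossing to 8.5 h, so it
shows intermediate killing. Cohort-level analysis
(`examples/03_population_comparison.py`) prints, for the default
simulated study,

```
nab_a450: population effect +0.644 (ln scale), se 0.093, p = 3.81e-12, sex-intercept sd 0.377
bka_ln_t: population effect +0.266 (ln scale), se 0.067, p = 7.24e-05, sex-intercept sd 0.156
reactive nAb vs total IgM: r^2 = 0.250 -> 75% of variance unexplained
```

i.e. the second population carries higher nAb levels and stronger killing
after accounting for sex, and total IgM explains only a quarter of the
variance in antigen-reactive IgM.

Each script in `examples/` exercises one capability; `nabassay --help`
shows the command-line surface (`simulate`, `bka`, `elisa`, `stats`,
`report`).

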