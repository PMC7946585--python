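# uuscore

Composite engagement scoring and longitudinal outcome analysis for
mobile diabetes-coaching programs.

## The problem

Mobile coaching apps for type 2 diabetes generate rich usage logs —
self-monitored blood glucose (SMBG) entries, dietary and exercise
records, coaching messages read — but whether the intervention improves
glycemic control depends heavily on how engaged each patient actually
is. `uuscore` implements the **user utility score (UUS)**, a simple
composite measure of early engagement, together with the full
longitudinal analysis used to relate it to glycated hemoglobin
(HbA1c) over a 12-month follow-up. It is aimed at biostatisticians and
digital-health researchers who want to score engagement cohorts, re-run
the analysis on their own data, or study the method's behaviour by
simulation.

## The score and the models

For each participant, the first 3 months (91 days) of app usage are
summarized into four components: days with an SMBG entry, days with a
dietary record, days with an exercise record, and the percentage of
coaching messages read. Each component is cut at the cohort's empirical
1/3 and 2/3 quantiles (tertiles T1/T2/T3, scored 0/1/2; inverted-ECDF
quantiles, ties to the lower tertile), and

```
UUS = s_smbg + s_diet + s_exercise + s_read   ∈ {0, …, 8}.
```

The cohort is split at the median UUS into low/high engagement groups
(ties at the threshold go low; a median of 4.5 gives UUS:0–4 vs
UUS:5–8). Downstream analysis then follows the standard longitudinal
battery:

* baseline group contrasts (Student t / Pearson chi-square);
* mixed between–within repeated-measures ANOVA of HbA1c over months
  0/3/6/12 (LOCF-completed);
* linear regressions of the HbA1c change Δ(M) = HbA1c(M) − HbA1c(0) on
  UUS, crude and with nested covariate sets — Model 1: age, sex;
  Model 2: + BMI, systolic BP, LDL, baseline HbA1c, diabetes duration;
  Model 3: + smoking, alcohol, ADS score;
* the reduction-rate regression, rate(M) = 100·Δ(M)/HbA1c(0) on UUS;
* Bonferroni correction across the three follow-up time points
  (0.05/3, printed threshold p < .016).

Missing month-12 visits are imputed by last observation carried forward
(LOCF) for the ANOVA and regressions; group contrasts of observed
changes use complete cases.

Because the motivating trial's data are private, the package ships a
calibrated synthetic-cohort generator (`trial_calibrated` scenario):
beta-binomial engagement over 91 days reproducing realistic tertile
cuts, Table-1-style baseline covariates, HbA1c trajectories with known
per-point UUS effects (−0.113 / −0.143 / −0.136 % per point at months
3/6/12), and group-differential month-12 dropout (39% vs 9%). All
validation is parameter recovery against these known truths.

## Worked example

```python
from uuscore import PipelineConfig, run_pipeline
results = run_pipeline(PipelineConfig(outdir="out",
                                      scenario="trial_calibrated", seed=7))
```

or, from the shell, `uuscore run --scenario trial_calibrated --seed 7
--outdir out`. On the packaged n=72 scenario this prints/writes
(`examples/03_full_analysis.py`):

```
Mixed between-within ANOVA on LOCF-completed HbA1c:
  between groups: F=1.70, p=0.197
  within time:    F=6.07, p=5.60e-04

Fully adjusted (Model 3) UUS coefficient on HbA1c change:
  month  3: beta=-0.181 (SE 0.071), p=0.014, n=72
  month  6: beta=-0.155 (SE 0.082), p=0.064, n=72
  month 12: beta=-0.203 (SE 0.093), p=0.034, n=72
```

Each Model-3 beta is the expected extra HbA1c change (in %) per
additional UUS point after covariate adjustment; at n=72 these scatter
widely around the generative truths (−0.113/−0.143/−0.136), which is
exactly the sampling noise a cohort of that size implies. The ANOVA line
tests whether the low/high engagement groups differ in their HbA1c
trajectories. `examples/04_parameter_recovery.py` shows the same
estimates concentrating on the truths as cohorts grow.

The `examples/` scripts cover each capability: hand-built log scoring
(01), cohort simulation (02), the full pipeline (03), and parameter
recovery (04). The CLI subcommands `simulate`, `score`, `analyze`,
`report` and `run` expose the same stages on CSV files; see
`uuscore --help`.

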