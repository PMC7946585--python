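# Methods

## The user utility score

Engagement over a fixed scoring window (days 1–91; "3 months" is treated
as exactly 91 days, consistent with component ranges that top out at 91)
is summarized per participant as four components: SMBG-entry days,
diet-record days, exercise-record days, and the message reading rate
100·Σread/Σsent. A "day" counts as engaged when at least one record of
that type exists on that calendar day. Each component is discretized at
the cohort's empirical 1/3 and 2/3 quantiles and scored 0/1/2; the UUS
is the sum (0–8).

Numerical conventions, chosen once and fixed:

* **Quantile definition** — inverted ECDF (nearest lower rank). On
  integer day counts this produces integer cut points, so tertile
  classes are describable as inclusive ranges (e.g. 0–33 / 34–75 /
  76–91 days).
* **Ties at a cut** go to the lower tertile (class membership uses ≤).
* **Zero denominator** — a participant with no messages sent in the
  window gets read rate 0 and a `read_rate_undefined` flag. With
  twice-weekly scheduled messages this cannot occur in generated data;
  the convention is conservative for observed data.
* **Degenerate components** — if every cohort value is identical the
  cuts collapse and all participants score 0 on that component, with a
  warning.
* **Median split** — threshold = cohort median, floored when
  non-integer; ties at the threshold go low; an all-identical score
  vector is an error. Group labels are reported as ranges
  (`UUS:0-4` / `UUS:5-8`).

The 0–8 range, the component set and the equal weighting are the
method's definition, not tunables; alternative weightings are out of
scope.

## Longitudinal analysis

Visits occur at months 0/3/6/12. LOCF replaces any missing
post-baseline value by the most recent earlier observed value of the
same outcome; it requires an observed baseline (hard error otherwise),
never alters observed values, and is idempotent. Questionnaire
outcomes (SDSCA subscales, ADS) are structurally absent at month 3 —
not administered, hence not imputed. Group contrasts of changes from
baseline use observed cases; the mixed ANOVA and all regressions use
LOCF-completed data. The complete-case behaviour is available via the
`use_locf` flag / `--complete-case`.

Statistics:

* Student (pooled-variance) t-tests by default, Welch by flag.
* Pearson chi-square without continuity correction.
* Mixed between–within ANOVA (group × time, 4 levels) via
  `pingouin.mixed_anova`; no sphericity correction by default,
  Greenhouse–Geisser by flag. For the balanced case the implementation
  agrees with a brute-force partitioned sums-of-squares decomposition
  to 1e-8 (tested); for unbalanced groups pingouin's cell-mean
  convention applies.
* OLS regressions of the HbA1c change on UUS (continuous 0–8) with
  nested covariate sets; covariate coding sex male=0/female=1,
  smoking/alcohol current=1. Rank-deficient designs raise an error
  naming near-collinear columns.
* Reduction rate = 100·(follow-up − baseline)/baseline (%, signed);
  simple regression on UUS.
* Bonferroni: alpha/m reported exactly and truncated (floored) to 3
  decimals, matching the convention of printing the cutoff as p < .016
  for m=3.
* Two-sided p-values throughout; nominal alpha 0.05.

## The synthetic cohort generator

The generator emulates a 72-participant, 91-day coaching cohort with
known ground truth; it exists because the motivating trial's data are
available only on request from the insurer, so all validation is
simulation-based.

* **Engagement** — each participant draws a latent daily propensity per
  component, p ~ Beta(α, β); day flags are independent Bernoulli(p), so
  day counts are beta-binomial (bounded, over-dispersed, heavy zero
  mass where α < 1). The packaged shapes were calibrated by solving the
  Beta quantile equations so the large-cohort tertile cuts land on
  realistic boundaries: SMBG Beta(0.614, 0.473) → cuts 33/75 days, diet
  Beta(0.294, 0.792) → 3/30, exercise Beta(0.545, 0.363) → 37/81, read
  probability Beta(1.024, 0.316) → 73%/97% (read rates are multiples of
  100/26 with the 26-message schedule, so the upper cut is matched to
  within one message). Messages are sent on a fixed twice-weekly
  schedule.
* **Covariates** — independent truncated normals / Bernoullis with
  means, SDs and proportions typical of an insured middle-aged type 2
  diabetes cohort (mean age ≈ 51, BMI ≈ 26 kg/m², baseline
  HbA1c ≈ 8.1%, ≈ 26% current smokers, …). Independence from
  engagement is deliberate: it makes adjusted and structural
  coefficients coincide, so recovery checks are clean. Confounding can
  be introduced by editing a scenario, but no packaged scenario does.
* **HbA1c trajectories** — at month M the change from baseline is
  β_M·UUS + γ·(baseline − cohort mean) + ε_M with ε_M ~ N(0, σ_M),
  independent across visits. The calibrated scenario uses the
  fully adjusted effect estimates β = (−0.113, −0.143, −0.136) %/point,
  regression-to-the-mean γ = −0.3 per % and σ = 1.0%, in line with
  reported change SDs (≈ 0.7–1.4%). A rate-scale variant
  (`trial_calibrated_rate`) applies the same linear predictor to the
  percent reduction rate — slopes (−2.70, −3.35, −3.19) %/point,
  σ = 12.5 rate-% — so the reduction-rate regression has an exactly
  linear generative analogue. An optional per-visit intercept
  (`intercept_by_visit`, default 0) adds population-level drift; see
  the LOCF caveat below for why the packaged scenarios leave it at 0.
* **Secondary outcomes** — baseline plus noise (SDs in line with
  reported change SDs) and a configurable UUS effect, default 0: the
  motivating analysis found no secondary-outcome association, so the
  null is the packaged truth.
* **Dropout** — month-12 records are lost with probability 0.3947 in
  the low group and 0.0882 in the high group (the observed 15/38 vs
  3/34 loss), missing completely at random *within* group; months 0–6
  are always complete. Only group-level loss rates are known, so no
  outcome-dependent missingness is modelled.
* **Reproducibility** — one global seed; engagement, baseline, outcomes
  and dropout each use a deterministic `SeedSequence` substream, so
  identical configurations are bit-identical and stages can be rerun
  in isolation.

What the generator does **not** emulate: within-day timing, message
content, behavioural feedback between coaching and engagement,
correlation between engagement and covariates, serial correlation of
HbA1c residuals across visits, enrolment-anchored windows. Passing
recovery tests therefore show the *pipeline* is correct and unbiased
under these conditions, not that the effect estimates from any real
cohort are unbiased.

### LOCF under differential dropout

With group-differential dropout, LOCF makes the month-12 regression
estimand a mixture: dropouts contribute their month-6 change. If the
month-6 and month-12 generative models differ (different β or different
population-level drift), the recovered month-12 coefficient is biased
away from the structural β₁₂ by roughly the dropout-weighted
difference — with a per-visit drift difference of 0.07% we measured a
bias near −0.009 %/point at n=5000. This is a genuine property of LOCF,
not an implementation artifact, and it is why the packaged scenarios
keep zero intercepts (β₆ ≈ β₁₂ leaves only a negligible residual
mixture term). Anyone studying LOCF bias can reintroduce
`intercept_by_visit` in a scenario file.

## Validation design and problem sizes

* **Parameter recovery** — 20 cohorts of n=5000 per scenario; the mean
  recovered coefficient is compared to truth within 3 Monte-Carlo
  standard errors. These sizes put the MC SE near 0.002 %/point, small
  enough to detect calibration errors an order of magnitude below the
  effect sizes while keeping the whole suite fast on one CPU.
* **Type-I error** — 1000 null-scenario cohorts of n=200; the crude
  regression's rejection rate at alpha 0.05 must land in 0.03–0.07
  (binomial 3σ band ≈ ±0.021).
* **Oracles** — every statistic is cross-checked against an
  independent closed form or brute-force computation (pooled-variance t
  formula, hand-computed chi-square, partitioned sums of squares,
  normal equations, rank-into-thirds tertiles) at 1e-8 relative
  tolerance on small instances.

## Known limitations

* No mixed-effects longitudinal models or multiple imputation; LOCF is
  the only missing-data strategy (by design, with the bias caveat
  above).
* Tertile cuts are cohort-relative: scores are not comparable across
  cohorts without refitting cuts, and near-duplicate values can make
  tertile classes markedly unequal.
* The unbalanced-groups ANOVA follows pingouin's sums-of-squares
  convention; other software (e.g. Type III with unweighted means) can
  differ slightly in the time main effect.
* `window_days` other than 91 are supported but the packaged
  calibrations assume the 91-day window.
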