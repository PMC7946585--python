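# Null scenario: identical to trial_calibrated except every true UUS effect
# is zero (HbA1c changes are regression-to-the-mean plus noise only).  Used
# for type-I-error calibration of the analysis pipeline.
n_participants: 72
study_days: 91
messages_per_week: 2
seed: 0
engagement:
  smbg: {kind: beta, alpha: 0.614, beta: 0.473}
  diet: {kind: beta, alpha: 0.294, beta: 0.792}
  exercise: {kind: beta, alpha: 0.545, beta: 0.363}
  read_prob: {kind: beta, alpha: 1.024, beta: 0.316}
covariates:
  continuous:
    age: {mean: 51.43, sd: 7.9}
    bmi: {mean: 26.04, sd: 3.3}
    sbp: {mean: 137.1, sd: 16.0}
    dbp: {mean: 87.03, sd: 10.4}
    hba1c_baseline: {mean: 8.13, sd: 1.46}
    total_chol: {mean: 170.06, sd: 32.6}
    tg: {mean: 146.9, sd: 61.2}
    hdl: {mean: 47.37, sd: 11.3}
    ldl: {mean: 93.19, sd: 30.0}
    dm_duration: {mean: 7.26, sd: 5.2}
    sdsca_diet: {mean: 11.04, sd: 6.0}
    sdsca_exercise: {mean: 6.03, sd: 4.0}
    sdsca_glucose: {mean: 3.92, sd: 4.8}
    sdsca_foot: {mean: 3.35, sd: 3.8}
    ads_total: {mean: 19.49, sd: 4.4}
  binary:
    male: 0.583
    smoker: 0.264
    drinker: 0.417
    insulin: 0.222
    antihypertensive: 0.375
    antidyslipidemic: 0.528
effects:
  scale: change
  beta_uus_by_visit: {3: 0.0, 6: 0.0, 12: 0.0}
  intercept_by_visit: {3: 0.0, 6: 0.0, 12: 0.0}
  gamma_baseline_hba1c: -0.3
  residual_sd_by_visit: {3: 1.0, 6: 1.0, 12: 1.0}
  secondary_effects: {}
  secondary_sd:
    bmi: 0.9
    sbp: 15.5
    dbp: 9.4
    total_chol: 33.0
    tg: 66.0
    hdl: 7.2
    ldl: 29.0
    sdsca_diet: 6.5
    sdsca_exercise: 3.4
    sdsca_glucose: 5.8
    sdsca_foot: 5.2
    ads_total: 4.7
dropout:
  low: 0.3947
  high: 0.0882
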