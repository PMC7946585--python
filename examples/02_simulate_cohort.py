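"""Simulate a calibrated synthetic trial cohort and inspect it.

Loads the packaged `trial_calibrated` scenario (n=72, 91 study days,
true per-point UUS effects on HbA1c change of -0.113/-0.143/-0.136 at
months 3/6/12, month-12 dropout of 39%/9% by group) and prints what the
generator produced.
"""

from uuscore import load_scenario, simulate_cohort

config = load_scenario("trial_calibrated")
cohort = simulate_cohort(config)

print(f"Simulated {config.n_participants} participants over "
      f"{config.study_days} days (seed {config.seed})\n")
print("Engagement tertile cuts derived from this cohort:")
for comp, cuts in cohort.cuts.items():
    print(f"  {comp:<14} {cuts.cut1:6.1f} / {cuts.cut2:6.1f}")
sizes = cohort.uus["group"].value_counts()
print(f"\nMedian split at UUS <= {cohort.threshold}: "
      f"low n={sizes['low']}, high n={sizes['high']}")
m12 = cohort.visits[cohort.visits["visit_month"] == 12]
print(f"Month-12 visits observed: {int(m12['observed'].sum())} of {len(m12)} "
      "(group-differential loss to follow-up)")
# The cuts vary around the calibration targets (33/75, 3/30, 37/81 days,
# 73/97 %) with cohort sampling noise; the dropout indicator is MCAR
# within each engagement group.
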