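"""Run the complete analysis pipeline on a simulated cohort.

Simulate -> score -> LOCF -> group tables, mixed ANOVA, adjusted
regressions and the reduction-rate model, writing every artifact to
an output directory and printing the headline results.
"""

import json
from pathlib import Path

from uuscore import PipelineConfig, run_pipeline

outdir = Path("scratch/example_run")
results = run_pipeline(PipelineConfig(outdir=outdir,
                                      scenario="trial_calibrated", seed=7))

anova = results["anova"]
print("Mixed between-within ANOVA on LOCF-completed HbA1c:")
print(f"  between groups: F={anova['between_group']['F']:.2f}, "
      f"p={anova['between_group']['p']:.3f}")
print(f"  within time:    F={anova['within_time']['F']:.2f}, "
      f"p={anova['within_time']['p']:.2e}")

print("\nFully adjusted (Model 3) UUS coefficient on HbA1c change:")
t3 = results["table3"]
for _, row in t3[t3["model"] == "model3"].iterrows():
    print(f"  month {int(row['visit_month']):>2}: beta={row['beta']:+.3f} "
          f"(SE {row['se']:.3f}), p={row['p_value']:.3f}, n={int(row['n'])}")

print("\nReduction-rate slope (percent of baseline per UUS point):")
for _, row in results["table4"].iterrows():
    print(f"  month {int(row['visit_month']):>2}: beta={row['beta']:+.2f} "
          f"(SE {row['se']:.2f}), p={row['p_value']:.3f}")

print(f"\nAll tables written to {outdir}/ "
      f"({', '.join(sorted(json.loads((outdir / 'manifest.json').read_text())['outputs']))})")
# At n=72 the coefficients scatter widely around the generative truths
# (-0.113/-0.143/-0.136); example 04 shows they concentrate there as n grows.
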