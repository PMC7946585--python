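"""Simulation-based validation: parameter recovery and type-I error.

These experiments run the *entire* analysis chain — daily logs through
tertile scoring, outcome generation, dropout, LOCF and regression — on
synthetic cohorts with known ground truth, and ask whether the pipeline
gives back what was put in.  They are the package's substitute for
external validation data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import inference, longitudinal, scoring, simulate
from .config import FOLLOWUP_MONTHS, SimulationConfig


def _analyze_cohort(config: SimulationConfig):
    """Simulate one cohort and prepare LOCF-completed changes and rates."""
    cohort = simulate.simulate_cohort(config)
    filled, imputed = longitudinal.locf_impute(cohort.visits)
    changes = longitudinal.change_from_baseline(filled, "hba1c", imputed)
    wide = filled.pivot(index="participant_id", columns="visit_month",
                        values="hba1c")
    rates = pd.concat([
        pd.DataFrame({"participant_id": wide.index, "visit_month": m,
                      "rate": longitudinal.reduction_rate(wide[0], wide[m])})
        for m in FOLLOWUP_MONTHS], ignore_index=True).merge(
        cohort.uus[["participant_id", "uus_total"]], on="participant_id")
    return cohort, changes, rates


def model_recovery(config: SimulationConfig, seeds,
                   model: str = "model3",
                   months=FOLLOWUP_MONTHS) -> pd.DataFrame:
    """Fit the UUS regression on one simulated cohort per seed.

    Returns a long frame (seed, visit_month, beta, se, n).  The month-12
    fit runs after group-differential dropout and LOCF, exactly as the
    pipeline would.
    """
    rows = []
    for seed in seeds:
        cohort, changes, _ = _analyze_cohort(config.replace(seed=int(seed)))
        for month in months:
            r = inference.fit_uus_model(changes, cohort.uus, cohort.baseline,
                                        model, month)
            rows.append({"seed": int(seed), "visit_month": month,
                         "beta": r.beta, "se": r.se, "n": r.n})
    return pd.DataFrame(rows)


def rate_recovery(config: SimulationConfig, seeds,
                  month: int = 12) -> pd.DataFrame:
    """Fit the reduction-rate regression on one simulated cohort per seed."""
    rows = []
    for seed in seeds:
        _, _, rates = _analyze_cohort(config.replace(seed=int(seed)))
        r = inference.fit_rate_model(rates, month)
        rows.append({"seed": int(seed), "visit_month": month,
                     "beta": r.beta, "se": r.se, "n": r.n})
    return pd.DataFrame(rows)


def summarize_recovery(fits: pd.DataFrame, truth_by_month) -> pd.DataFrame:
    """Mean estimate, Monte-Carlo SE and z vs truth, per visit month."""
    rows = []
    for month, sub in fits.groupby("visit_month"):
        est = sub["beta"].to_numpy()
        mcse = est.std(ddof=1) / np.sqrt(len(est))
        truth = truth_by_month[month]
        rows.append({"visit_month": month, "n_seeds": len(est),
                     "mean_beta": est.mean(), "mc_se": mcse,
                     "truth": truth, "z": (est.mean() - truth) / mcse})
    return pd.DataFrame(rows)


def type_one_error(config: SimulationConfig, replicates: int,
                   base_seed: int = 10_000, month: int = 3,
                   model: str = "crude", alpha: float = 0.05) -> float:
    """Empirical rejection rate of the UUS regression under a null scenario.

    ``config`` should have all true UUS effects equal to zero; the
    returned rate estimates the test's type-I error at level ``alpha``.
    Dropout is skipped (months 3/6 are always complete anyway and the
    null makes group-differential loss uninformative).
    """
    hits = 0
    for i in range(replicates):
        cfg = config.replace(seed=int(base_seed + i))
        logs = simulate.generate_engagement_logs(cfg)
        baseline = simulate.generate_baseline(cfg)
        summaries = scoring.summarize_engagement(logs, cfg.study_days)
        cuts = {c: scoring.compute_tertile_cuts(summaries[c], c)
                for c in scoring.COMPONENTS}
        uus, _ = scoring.split_by_median(scoring.compute_uus(summaries, cuts))
        totals = dict(zip(uus["participant_id"], uus["uus_total"]))
        visits = simulate.generate_outcomes(cfg, totals, baseline)
        changes = longitudinal.change_from_baseline(visits, "hba1c")
        r = inference.fit_uus_model(changes, uus, baseline, model, month)
        hits += (r.p < alpha)
    return hits / replicates
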