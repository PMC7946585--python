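"""Synthetic cohort generation with known ground-truth effects.

The trial data this package analyses are not public, so validation rests
on simulation: cohorts are generated from a :class:`~uuscore.config.
SimulationConfig` whose engagement distributions, baseline covariates,
true longitudinal UUS effects and group-differential dropout are all
explicit — the downstream pipeline can then be checked for parameter
recovery, type-I error and reproducibility.

Randomness: one global seed; each stage (engagement, baseline, outcomes,
dropout) draws from its own deterministic substream, so identical
configurations yield bit-identical cohorts and stages can be re-run in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import scoring
from .config import (
    BINARY_COVARIATES,
    CONTINUOUS_COVARIATES,
    COUNT_COMPONENTS,
    FOLLOWUP_MONTHS,
    SECONDARY_OUTCOMES,
    _CLIP_MIN,
    ComponentDist,
    SimulationConfig,
)
from .errors import ConfigurationError, ValidationError
from .io import VISIT_COLUMNS

_STAGES = {"engagement": 0, "baseline": 1, "outcomes": 2, "dropout": 3}

#: questionnaire outcomes not administered at the month-3 visit
QUESTIONNAIRE_OUTCOMES = ("sdsca_diet", "sdsca_exercise", "sdsca_glucose",
                          "sdsca_foot", "ads_total")


def _substream(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STAGES[stage],)))


def participant_ids(n: int) -> list[str]:
    return [f"P{i:05d}" for i in range(1, n + 1)]


def message_schedule(study_days: int, messages_per_week: int) -> np.ndarray:
    """Days (1-based) on which a coaching message is sent.

    Messages are spread evenly within each 7-day week; with the default
    two per week over 91 days this yields 26 scheduled messages.
    """
    offsets = np.floor((np.arange(messages_per_week) + 0.5)
                       * 7 / messages_per_week).astype(int)
    weeks = np.arange(0, study_days, 7)
    days = (weeks[:, None] + offsets[None, :] + 1).ravel()
    return days[days <= study_days]


def _draw_propensity(dist: ComponentDist, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    if dist.kind == "beta":
        return rng.beta(dist.alpha, dist.beta, n)
    return np.full(n, dist.p)


def generate_engagement_logs(config: SimulationConfig) -> pd.DataFrame:
    """Generate the daily engagement log table.

    Each participant gets a latent daily propensity per component (drawn
    from the configured Beta, so day counts are beta-binomial and
    over-dispersed); record flags are independent Bernoulli days.
    Messages follow the fixed schedule and are read independently with a
    per-participant read probability.
    """
    config.validate()
    n, days = config.n_participants, config.study_days
    rng = _substream(config.seed, "engagement")
    ids = participant_ids(n)

    props = {c: _draw_propensity(getattr(config.engagement, c), n, rng)
             for c in COUNT_COMPONENTS}
    p_read = _draw_propensity(config.engagement.read_prob, n, rng)

    flags = {c: rng.random((n, days)) < props[c][:, None]
             for c in COUNT_COMPONENTS}
    sched = message_schedule(days, config.messages_per_week)
    sent = np.zeros((n, days), dtype=np.int64)
    sent[:, sched - 1] = 1
    read = np.where(rng.random((n, days)) < p_read[:, None], sent, 0)

    return pd.DataFrame({
        "participant_id": np.repeat(ids, days),
        "day": np.tile(np.arange(1, days + 1), n),
        "smbg_recorded": flags["smbg"].ravel(),
        "diet_recorded": flags["diet"].ravel(),
        "exercise_recorded": flags["exercise"].ravel(),
        "messages_sent": sent.ravel(),
        "messages_read": read.ravel(),
    })


def generate_baseline(config: SimulationConfig) -> pd.DataFrame:
    """Generate the baseline covariate table (independent of engagement)."""
    config.validate()
    n = config.n_participants
    rng = _substream(config.seed, "baseline")
    data: dict = {"participant_id": participant_ids(n)}
    for name in CONTINUOUS_COVARIATES:
        mean, sd = config.covariates.continuous[name]
        data[name] = np.maximum(rng.normal(mean, sd, n), _CLIP_MIN[name])
    for name in BINARY_COVARIATES:
        data[name] = rng.random(n) < config.covariates.binary[name]
    df = pd.DataFrame(data)
    df["sex"] = np.where(df.pop("male"), "male", "female")
    from .io import BASELINE_COLUMNS
    return df[list(BASELINE_COLUMNS)]


def generate_outcomes(config: SimulationConfig, uus_totals,
                      baseline: pd.DataFrame) -> pd.DataFrame:
    """Generate the longitudinal visit table from true UUS effects.

    At each follow-up month M the HbA1c linear predictor is

        intercept_M + beta_M * UUS + gamma * (baseline - mean baseline) + eps

    interpreted as an absolute change (scale ``change``) or as a percent
    reduction rate applied to baseline (scale ``rate``).  Secondary
    outcomes evolve as baseline plus their configured UUS effect
    (default zero) plus noise; questionnaire scales are structurally
    absent at month 3.  All visits are generated as observed — apply
    :func:`apply_dropout` afterwards for month-12 loss to follow-up.
    """
    config.validate()
    effects = config.effects
    for month in FOLLOWUP_MONTHS:
        if month not in effects.beta_uus_by_visit:
            raise ConfigurationError(
                f"effects.beta_uus_by_visit.{month}",
                "no true effect configured for this visit")
    uus = np.array([uus_totals[p] for p in baseline["participant_id"]],
                   dtype=float)
    if uus.min() < 0 or uus.max() > scoring.UUS_MAX:
        raise ValidationError(
            f"UUS totals must lie in [0, {scoring.UUS_MAX}]")
    rng = _substream(config.seed, "outcomes")
    b = baseline["hba1c_baseline"].to_numpy(dtype=float)
    centered = b - b.mean()
    n = len(baseline)

    rows = []
    month0 = {"participant_id": baseline["participant_id"],
              "visit_month": 0, "hba1c": b}
    for name in SECONDARY_OUTCOMES:
        base_col = "hba1c_baseline" if name == "hba1c" else name
        month0[name] = baseline[base_col].to_numpy(dtype=float)
    rows.append(pd.DataFrame(month0))

    for month in FOLLOWUP_MONTHS:
        lp = (effects.intercept_by_visit.get(month, 0.0)
              + effects.beta_uus_by_visit[month] * uus
              + effects.gamma_baseline_hba1c * centered
              + rng.normal(0.0, effects.residual_sd_by_visit[month], n))
        if effects.scale == "rate":
            hba1c = b * (1.0 + lp / 100.0)
        else:
            hba1c = b + lp
        visit = {"participant_id": baseline["participant_id"],
                 "visit_month": month, "hba1c": hba1c}
        for name in SECONDARY_OUTCOMES:
            sd = effects.secondary_sd.get(name, 0.0)
            eff = effects.secondary_effects.get(name, 0.0)
            value = (baseline[name].to_numpy(dtype=float)
                     + eff * uus + rng.normal(0.0, sd, n))
            if month == 3 and name in QUESTIONNAIRE_OUTCOMES:
                value = np.full(n, np.nan)
            visit[name] = value
        rows.append(pd.DataFrame(visit))

    out = pd.concat(rows, ignore_index=True)
    out["observed"] = True
    out = out.sort_values(["participant_id", "visit_month"],
                          ignore_index=True)
    return out[list(VISIT_COLUMNS)]


def apply_dropout(visits: pd.DataFrame, groups, config: SimulationConfig,
                  seed: int | None = None) -> pd.DataFrame:
    """Flag month-12 visits missing with group-specific probability.

    ``groups`` maps every participant to ``"low"`` or ``"high"``;
    dropout is MCAR within group.  Months 0/3/6 are never removed.
    """
    config.dropout.validate()
    ids = sorted(visits["participant_id"].unique())
    missing = [p for p in ids if p not in groups]
    if missing:
        raise ValidationError(
            f"participants without a group assignment: {missing[:5]}")
    rng = _substream(config.seed if seed is None else seed, "dropout")
    p_by_group = {"low": config.dropout.low, "high": config.dropout.high}
    probs = np.array([p_by_group[groups[p]] for p in ids])
    dropped = {p for p, d in zip(ids, rng.random(len(ids)) < probs) if d}

    out = visits.copy()
    mask = (out["visit_month"] == 12) & out["participant_id"].isin(dropped)
    out.loc[mask, list(_outcome_cols(out))] = np.nan
    out.loc[mask, "observed"] = False
    return out


def _outcome_cols(visits: pd.DataFrame):
    from .io import VISIT_OUTCOMES
    return [c for c in VISIT_OUTCOMES if c in visits.columns]


@dataclass
class SimulatedCohort:
    """Everything one simulated study produces, pre-wired through scoring."""

    config: SimulationConfig
    logs: pd.DataFrame
    baseline: pd.DataFrame
    visits: pd.DataFrame          # post-dropout
    summaries: pd.DataFrame
    cuts: dict[str, scoring.TertileCuts]
    uus: pd.DataFrame             # with group labels
    threshold: int


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Run the full generative chain: logs → UUS → outcomes → dropout."""
    logs = generate_engagement_logs(config)
    baseline = generate_baseline(config)
    summaries = scoring.summarize_engagement(logs, config.study_days)
    cuts = {c: scoring.compute_tertile_cuts(summaries[c], c)
            for c in scoring.COMPONENTS}
    uus, threshold = scoring.split_by_median(
        scoring.compute_uus(summaries, cuts))
    totals = dict(zip(uus["participant_id"], uus["uus_total"]))
    visits = generate_outcomes(config, totals, baseline)
    groups = dict(zip(uus["participant_id"], uus["group"]))
    visits = apply_dropout(visits, groups, config)
    return SimulatedCohort(config=config, logs=logs, baseline=baseline,
                           visits=visits, summaries=summaries, cuts=cuts,
                           uus=uus, threshold=threshold)
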