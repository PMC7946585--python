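"""End-to-end orchestration: simulate → score → analyze → report.

Every stage reads and writes plain CSV/JSON artifacts, so each is also
consumable on its own (the CLI exposes them as subcommands).  A run is
fully determined by its :class:`PipelineConfig`: rerunning with an
identical configuration reproduces every output byte for byte.  The
report bundle is stamped with a hash of the configuration and the seed
in ``manifest.json``.

Analysis conventions follow the study design: group contrasts of
observed changes use complete cases (the month-12 column therefore has
fewer participants), while the repeated-measures ANOVA and all
regressions use LOCF-completed data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import inference, io, longitudinal, scoring, simulate
from .config import FOLLOWUP_MONTHS, SimulationConfig, load_scenario
from .errors import ConfigurationError, UUScoreError

logger = logging.getLogger("uuscore")

#: baseline characteristics reported in the group-comparison table
_TABLE1_CONTINUOUS = (
    ("age", "Age (years)"), ("bmi", "Body mass index (kg/m2)"),
    ("sbp", "Systolic blood pressure (mmHg)"),
    ("dbp", "Diastolic blood pressure (mmHg)"),
    ("hba1c_baseline", "HbA1c (%)"),
    ("total_chol", "Total cholesterol (mg/dL)"),
    ("tg", "Triglyceride (mg/dL)"), ("hdl", "HDL cholesterol (mg/dL)"),
    ("ldl", "LDL cholesterol (mg/dL)"),
    ("dm_duration", "Diabetes duration (years)"),
    ("sdsca_diet", "SDSCA diet total"), ("sdsca_exercise", "SDSCA exercise"),
    ("sdsca_glucose", "SDSCA blood glucose testing"),
    ("sdsca_foot", "SDSCA foot care"), ("ads_total", "ADS total"),
)
_TABLE1_BINARY = (
    ("smoker", "Current smoker"), ("drinker", "Current alcohol drinker"),
    ("insulin", "Insulin injection"),
    ("antihypertensive", "Antihypertensive medication"),
    ("antidyslipidemic", "Antidyslipidemic medication"),
)
_TABLE1_SEX = ("sex", "Female sex")

_SECONDARY_TABLE_OUTCOMES = (
    "bmi", "sbp", "dbp", "total_chol", "tg", "hdl", "ldl",
    "sdsca_diet", "sdsca_exercise", "sdsca_glucose", "sdsca_foot",
    "ads_total",
)


@dataclass(frozen=True)
class PipelineConfig:
    """One reproducible pipeline run.

    Exactly one of ``scenario`` (packaged name or YAML path, simulated
    input) or the three input paths (observed input) must be given.
    """

    outdir: str | Path
    scenario: str | None = None
    logs_path: str | Path | None = None
    baseline_path: str | Path | None = None
    visits_path: str | Path | None = None
    window_days: int = 91
    use_locf: bool = True
    sphericity_correction: bool = False
    welch: bool = False
    alpha: float = 0.05
    seed: int | None = None
    n_participants: int | None = None

    def validate(self) -> None:
        paths = (self.logs_path, self.baseline_path, self.visits_path)
        have_paths = all(p is not None for p in paths)
        some_paths = any(p is not None for p in paths)
        if self.scenario is not None and some_paths:
            raise ConfigurationError(
                "scenario", "give either a scenario or input paths, not both")
        if self.scenario is None and not have_paths:
            raise ConfigurationError(
                "scenario", "either a scenario or all three input paths required")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha", f"must be in (0, 1), got {self.alpha}")

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d = {k: (str(v) if isinstance(v, Path) else v) for k, v in d.items()}
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _stage(name: str):
    """Decorator: prefix stage name onto any package error it raises."""
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except UUScoreError as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc
        inner.__name__ = fn.__name__
        return inner
    return wrap


@_stage("simulate")
def simulate_stage(config: SimulationConfig, outdir: Path) -> dict[str, Path]:
    """Generate a cohort and write the three input CSVs."""
    cohort = simulate.simulate_cohort(config)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"logs": outdir / "logs.csv", "baseline": outdir / "baseline.csv",
             "visits": outdir / "visits.csv"}
    io.write_logs(cohort.logs, paths["logs"])
    io.write_baseline(cohort.baseline, paths["baseline"])
    io.write_visits(cohort.visits, paths["visits"])
    logger.info("simulated cohort of %d participants -> %s",
                config.n_participants, outdir)
    return paths


@_stage("score")
def score_stage(logs: pd.DataFrame, window_days: int, outdir: Path):
    """Summarize engagement, derive tertile cuts, score and split."""
    summaries = scoring.summarize_engagement(logs, window_days)
    cuts = {c: scoring.compute_tertile_cuts(summaries[c], c)
            for c in scoring.COMPONENTS}
    uus, threshold = scoring.split_by_median(scoring.compute_uus(summaries, cuts))
    outdir.mkdir(parents=True, exist_ok=True)
    uus.to_csv(outdir / "uus.csv", index=False)
    cuts_doc = {c: {"cut1": cuts[c].cut1, "cut2": cuts[c].cut2}
                for c in scoring.COMPONENTS}
    cuts_doc["median_split"] = {
        "threshold": threshold,
        "labels": scoring.group_labels(threshold),
        "sizes": uus["group"].value_counts().to_dict(),
    }
    (outdir / "cuts.json").write_text(json.dumps(cuts_doc, indent=2,
                                                 sort_keys=True) + "\n")
    return summaries, cuts, uus, threshold


def _mean_sd(x: pd.Series) -> tuple[float, float]:
    return float(x.mean()), float(x.std(ddof=1))


def _table1(uus: pd.DataFrame, baseline: pd.DataFrame, welch: bool) -> pd.DataFrame:
    df = baseline.merge(uus[["participant_id", "group"]], on="participant_id")
    low, high = df[df["group"] == "low"], df[df["group"] == "high"]
    rows = []
    for col, label in _TABLE1_CONTINUOUS:
        (ml, sl), (mh, sh) = _mean_sd(low[col]), _mean_sd(high[col])
        _, p = inference.two_sample_t(low[col], high[col], welch=welch)
        rows.append({"characteristic": label, "kind": "continuous",
                     "low": f"{ml:.2f} ({sl:.2f})",
                     "high": f"{mh:.2f} ({sh:.2f})", "p_value": p})
    sex_counts = [[int((g["sex"] == "female").sum()),
                   int((g["sex"] == "male").sum())] for g in (low, high)]
    _, p, _ = inference.pearson_chi_square(np.transpose(sex_counts))
    rows.append({"characteristic": _TABLE1_SEX[1], "kind": "binary",
                 "low": f"{sex_counts[0][0]} ({100 * sex_counts[0][0] / len(low):.1f}%)",
                 "high": f"{sex_counts[1][0]} ({100 * sex_counts[1][0] / len(high):.1f}%)",
                 "p_value": p})
    for col, label in _TABLE1_BINARY:
        counts = [[int(g[col].sum()), int((~g[col].astype(bool)).sum())]
                  for g in (low, high)]
        _, p, _ = inference.pearson_chi_square(np.transpose(counts))
        rows.append({"characteristic": label, "kind": "binary",
                     "low": f"{counts[0][0]} ({100 * counts[0][0] / len(low):.1f}%)",
                     "high": f"{counts[1][0]} ({100 * counts[1][0] / len(high):.1f}%)",
                     "p_value": p})
    return pd.DataFrame(rows)


def _group_change_table(changes: pd.DataFrame, uus: pd.DataFrame,
                        welch: bool) -> pd.DataFrame:
    """Per-group mean (SD) of observed changes with Student t p-values."""
    merged = changes.merge(uus[["participant_id", "group"]], on="participant_id")
    rows = []
    for (outcome, month), sub in merged.groupby(["outcome", "visit_month"],
                                                sort=True):
        sub = sub.dropna(subset=["delta"])
        low = sub.loc[sub["group"] == "low", "delta"]
        high = sub.loc[sub["group"] == "high", "delta"]
        if len(low) < 2 or len(high) < 2:
            continue
        (ml, sl), (mh, sh) = _mean_sd(low), _mean_sd(high)
        _, p = inference.two_sample_t(low, high, welch=welch)
        rows.append({"outcome": outcome, "visit_month": month,
                     "low_n": len(low), "low_mean": ml, "low_sd": sl,
                     "high_n": len(high), "high_mean": mh, "high_sd": sh,
                     "p_value": p})
    return pd.DataFrame(rows)


@_stage("analyze")
def analyze_stage(uus: pd.DataFrame, baseline: pd.DataFrame,
                  visits: pd.DataFrame, cfg: PipelineConfig,
                  outdir: Path) -> dict:
    """All statistics: group tables, ANOVA, UUS and rate regressions."""
    outdir.mkdir(parents=True, exist_ok=True)
    filled, imputed = longitudinal.locf_impute(visits)
    analysis_visits = filled if cfg.use_locf else visits

    # observed (non-imputed) changes for the group contrast tables
    observed_changes = pd.concat(
        [longitudinal.change_from_baseline(visits, out)
         for out in ("hba1c", *_SECONDARY_TABLE_OUTCOMES)], ignore_index=True)
    locf_changes = longitudinal.change_from_baseline(
        analysis_visits, "hba1c", imputed if cfg.use_locf else None)

    table1 = _table1(uus, baseline, cfg.welch)
    table1.to_csv(outdir / "table1.csv", index=False)

    hba1c_obs = observed_changes[observed_changes["outcome"] == "hba1c"]
    table2 = _group_change_table(hba1c_obs, uus, cfg.welch)
    table2.to_csv(outdir / "table2.csv", index=False)

    rows = []
    for model in inference.MODEL_COVARIATES:
        for month in FOLLOWUP_MONTHS:
            r = inference.fit_uus_model(locf_changes, uus, baseline,
                                        model, month)
            rows.append({"model": model, "visit_month": month, "beta": r.beta,
                         "se": r.se, "p_value": r.p, "n": r.n})
    table3 = pd.DataFrame(rows)
    table3.to_csv(outdir / "table3.csv", index=False)

    wide = analysis_visits.pivot(index="participant_id",
                                 columns="visit_month", values="hba1c")
    base = wide[0]
    rate_rows = []
    for month in FOLLOWUP_MONTHS:
        rate_rows.append(pd.DataFrame({
            "participant_id": wide.index, "visit_month": month,
            "rate": longitudinal.reduction_rate(base, wide[month])}))
    rates = pd.concat(rate_rows, ignore_index=True).merge(
        uus[["participant_id", "uus_total"]], on="participant_id")
    table4 = pd.DataFrame([
        {"visit_month": m, "beta": r.beta, "se": r.se, "p_value": r.p, "n": r.n}
        for m in FOLLOWUP_MONTHS
        for r in [inference.fit_rate_model(rates, m)]])
    table4.to_csv(outdir / "table4.csv", index=False)

    secondary = observed_changes[observed_changes["outcome"] != "hba1c"]
    table5 = _group_change_table(secondary, uus, cfg.welch)
    table5.to_csv(outdir / "table5.csv", index=False)

    groups = dict(zip(uus["participant_id"], uus["group"]))
    anova = inference.mixed_anova(wide, groups,
                                  sphericity_correction=cfg.sphericity_correction)
    bonf = inference.bonferroni_threshold(cfg.alpha, len(FOLLOWUP_MONTHS))
    anova_doc = {
        "design": anova.design,
        "sphericity_corrected": anova.sphericity_corrected,
        "within_time": dataclasses.asdict(anova.within),
        "between_group": dataclasses.asdict(anova.between),
        "interaction": dataclasses.asdict(anova.interaction),
        "alpha": cfg.alpha,
        "bonferroni_threshold": {"exact": bonf.exact,
                                 "truncated": bonf.truncated, "m": bonf.m},
    }
    (outdir / "anova.json").write_text(json.dumps(anova_doc, indent=2,
                                                  sort_keys=True) + "\n")

    changes_out = locf_changes.copy()
    changes_out.to_csv(outdir / "changes.csv", index=False)
    return {"table1": table1, "table2": table2, "table3": table3,
            "table4": table4, "table5": table5, "anova": anova_doc}


@_stage("report")
def report_stage(outdir: Path) -> Path:
    """Render a plain-markdown summary from the analysis artifacts."""
    cuts = json.loads((outdir / "cuts.json").read_text())
    anova = json.loads((outdir / "anova.json").read_text())
    table2 = pd.read_csv(outdir / "table2.csv")
    table3 = pd.read_csv(outdir / "table3.csv")
    table4 = pd.read_csv(outdir / "table4.csv")
    split = cuts["median_split"]
    labels, sizes = split["labels"], split["sizes"]

    lines = ["# Engagement-score analysis summary", ""]
    lines.append(f"Median split at UUS <= {split['threshold']}: "
                 f"{labels['low']} (n={sizes.get('low', 0)}) vs "
                 f"{labels['high']} (n={sizes.get('high', 0)})")
    lines.append("")
    lines.append("Component tertile cuts (score 0 | 1 | 2):")
    for comp in scoring.COMPONENTS:
        c = cuts[comp]
        lines.append(f"- {comp}: <= {c['cut1']:g} | <= {c['cut2']:g} | above")
    lines.append("")
    lines.append(f"Mixed ANOVA (group x time): between-group "
                 f"F={anova['between_group']['F']:.2f}, "
                 f"p={anova['between_group']['p']:.4f}; within-time "
                 f"F={anova['within_time']['F']:.2f}, "
                 f"p={anova['within_time']['p']:.4g}")
    lines.append("")
    lines.append("HbA1c change from baseline, mean (SD) by group "
                 "[observed cases]:")
    for _, r in table2.iterrows():
        lines.append(f"- month {int(r['visit_month'])}: "
                     f"{labels['low']} {r['low_mean']:.2f} ({r['low_sd']:.2f}) "
                     f"n={int(r['low_n'])} vs {labels['high']} "
                     f"{r['high_mean']:.2f} ({r['high_sd']:.2f}) "
                     f"n={int(r['high_n'])}, p={r['p_value']:.3f}")
    lines.append("")
    lines.append("UUS coefficient on HbA1c change (LOCF), beta (SE) per model:")
    for _, r in table3.iterrows():
        lines.append(f"- {r['model']} month {int(r['visit_month'])}: "
                     f"{r['beta']:.3f} ({r['se']:.3f}), p={r['p_value']:.3f}")
    lines.append("")
    lines.append("Reduction-rate regression (percent of baseline per UUS point):")
    for _, r in table4.iterrows():
        lines.append(f"- month {int(r['visit_month'])}: {r['beta']:.2f} "
                     f"({r['se']:.2f}), p={r['p_value']:.3f}")
    bt = anova["bonferroni_threshold"]
    lines.append("")
    lines.append(f"Bonferroni threshold for {bt['m']} time points: "
                 f"p < {bt['truncated']:.3f} (exact {bt['exact']:.6f})")
    path = outdir / "summary.md"
    path.write_text("\n".join(lines) + "\n")
    return path


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage in order and return the report bundle."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if cfg.scenario is not None:
        sim = load_scenario(cfg.scenario)
        if cfg.seed is not None:
            sim = sim.replace(seed=cfg.seed)
        if cfg.n_participants is not None:
            sim = sim.replace(n_participants=cfg.n_participants)
        paths = simulate_stage(sim, outdir / "data")
    else:
        paths = {"logs": Path(cfg.logs_path),
                 "baseline": Path(cfg.baseline_path),
                 "visits": Path(cfg.visits_path)}

    logs = io.read_logs(paths["logs"])
    baseline = io.read_baseline(paths["baseline"])
    visits = io.read_visits(paths["visits"])

    _, cuts, uus, threshold = score_stage(logs, cfg.window_days, outdir)
    results = analyze_stage(uus, baseline, visits, cfg, outdir)
    report = report_stage(outdir)

    manifest = {"config_hash": cfg.config_hash(),
                "seed": cfg.seed,
                "scenario": cfg.scenario,
                "threshold": threshold,
                "outputs": sorted(p.name for p in outdir.glob("*.*"))}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    results["report"] = report
    results["uus"] = uus
    results["threshold"] = threshold
    return results
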