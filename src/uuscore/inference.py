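"""Statistical procedures for the engagement-score analysis.

Two-group contrasts (Student t, Pearson chi-square), the mixed
between–within repeated-measures ANOVA on HbA1c, covariate-adjusted
linear regressions of HbA1c change on the UUS (crude and Models 1–3),
the reduction-rate regression, and the Bonferroni threshold for the
three follow-up time points.

Covariate coding: sex male=0/female=1; smoking and alcohol current=1.
All p-values are two-sided.  The UUS always enters as a continuous 0–8
covariate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError

#: nested covariate sets for the adjusted models
MODEL_COVARIATES = {
    "crude": [],
    "model1": ["age", "sex_female"],
    "model2": ["age", "sex_female", "bmi", "sbp", "ldl", "hba1c_baseline",
               "dm_duration"],
    "model3": ["age", "sex_female", "bmi", "sbp", "ldl", "hba1c_baseline",
               "dm_duration", "smoker", "drinker", "ads_total"],
}


@dataclass(frozen=True)
class ModelResult:
    """One fitted UUS effect: coefficient, SE, p and model descriptor."""

    model: str
    outcome: str
    visit_month: int
    beta: float
    se: float
    p: float
    n: int
    covariates: tuple = ()


@dataclass(frozen=True)
class AnovaEffect:
    F: float
    df1: float
    df2: float
    p: float


@dataclass(frozen=True)
class AnovaResult:
    """Mixed between–within ANOVA: time, group and interaction effects."""

    within: AnovaEffect
    between: AnovaEffect
    interaction: AnovaEffect
    design: str = "one between factor (group) x one within factor (time)"
    sphericity_corrected: bool = False


def two_sample_t(x, y, welch: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test; Student (pooled variance) by default."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("each group needs >= 2 values for a t-test")
    res = stats.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def pearson_chi_square(table) -> tuple[float, float, int]:
    """Pearson chi-square test of independence, no continuity correction."""
    obs = np.asarray(table)
    if np.any(obs < 0) or np.any(obs % 1 != 0):
        raise ValidationError("counts must be non-negative integers")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValidationError("chi-square table has a zero margin")
    res = stats.chi2_contingency(obs, correction=False)
    return float(res.statistic), float(res.pvalue), int(res.dof)


def mixed_anova(values: pd.DataFrame, groups,
                sphericity_correction: bool = False) -> AnovaResult:
    """Mixed between–within repeated-measures ANOVA.

    Parameters
    ----------
    values
        Wide table: one row per participant (index = participant id),
        one column per visit month, fully observed (run LOCF first).
    groups
        Mapping participant id -> group label (two groups).
    sphericity_correction
        Apply the Greenhouse–Geisser correction to the within-subject
        and interaction p-values.

    The sums-of-squares decomposition is delegated to
    :func:`pingouin.mixed_anova`.
    """
    import pingouin as pg

    if values.isna().any().any():
        raise ValidationError("missing cells in the ANOVA matrix; apply LOCF first")
    labels = pd.Series({p: groups[p] for p in values.index})
    if labels.nunique() != 2:
        raise ValidationError("mixed_anova requires exactly two groups")
    long = values.reset_index(names="participant_id").melt(
        id_vars="participant_id", var_name="time", value_name="y")
    long["group"] = long["participant_id"].map(dict(labels))
    aov = pg.mixed_anova(data=long, dv="y", within="time",
                         subject="participant_id", between="group",
                         correction=sphericity_correction)
    aov = aov.set_index("Source")

    def effect(source: str, corrected: bool) -> AnovaEffect:
        row = aov.loc[source]
        p = row["p_GG_corr"] if (corrected and "p_GG_corr" in row
                                 and not pd.isna(row["p_GG_corr"])) else row["p_unc"]
        return AnovaEffect(F=float(row["F"]), df1=float(row["DF1"]),
                           df2=float(row["DF2"]), p=float(p))

    return AnovaResult(
        within=effect("time", sphericity_correction),
        between=effect("group", False),
        interaction=effect("Interaction", sphericity_correction),
        sphericity_corrected=sphericity_correction,
    )


def _design_frame(uus: pd.DataFrame, baseline: pd.DataFrame) -> pd.DataFrame:
    """Merge UUS totals with coded baseline covariates."""
    df = uus[["participant_id", "uus_total"]].merge(
        baseline, on="participant_id", validate="one_to_one")
    df["sex_female"] = (df["sex"] == "female").astype(float)
    for col in ("smoker", "drinker"):
        df[col] = df[col].astype(float)
    return df


def _ols(y: np.ndarray, X: pd.DataFrame, focal: str):
    """OLS via statsmodels; returns (beta, se, p) for the focal column."""
    import statsmodels.api as sm

    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        corr = np.abs(np.corrcoef(Xc.to_numpy(), rowvar=False))
        np.fill_diagonal(corr, 0.0)
        pairs = sorted({Xc.columns[i] for i in np.argwhere(corr > 0.9999).ravel()})
        raise ValidationError(
            f"design matrix is rank deficient (rank {rank} < {Xc.shape[1]}); "
            f"near-collinear columns: {pairs or list(Xc.columns)}")
    fit = sm.OLS(y, Xc).fit()
    return float(fit.params[focal]), float(fit.bse[focal]), float(fit.pvalues[focal])


def fit_uus_model(changes: pd.DataFrame, uus: pd.DataFrame,
                  baseline: pd.DataFrame, model: str,
                  visit_month: int, outcome: str = "hba1c") -> ModelResult:
    """Regress the change at one visit on UUS with a nested covariate set.

    ``model`` is one of ``crude``/``model1``/``model2``/``model3``
    (Model 1: age, sex; Model 2: + BMI, SBP, LDL, baseline HbA1c,
    diabetes duration; Model 3: + smoking, alcohol, ADS total).
    """
    if model not in MODEL_COVARIATES:
        raise ValidationError(f"unknown model {model!r}")
    sub = changes[(changes["visit_month"] == visit_month)
                  & (changes["outcome"] == outcome)]
    df = sub[["participant_id", "delta"]].merge(
        _design_frame(uus, baseline), on="participant_id",
        validate="one_to_one").dropna(subset=["delta"])
    covs = MODEL_COVARIATES[model]
    X = df[["uus_total", *covs]].astype(float)
    if len(df) <= X.shape[1] + 1:
        raise InsufficientDataError(
            f"n={len(df)} too small for {1 + len(covs)} predictors")
    beta, se, p = _ols(df["delta"].to_numpy(dtype=float), X, "uus_total")
    return ModelResult(model=model, outcome=outcome, visit_month=visit_month,
                       beta=beta, se=se, p=p, n=len(df),
                       covariates=tuple(covs))


def fit_rate_model(rates: pd.DataFrame, visit_month: int) -> ModelResult:
    """Simple regression of the HbA1c reduction rate on UUS at one visit.

    ``rates`` needs columns participant_id, visit_month, rate, uus_total.
    """
    sub = rates[rates["visit_month"] == visit_month].dropna(subset=["rate"])
    if len(sub) < 3:
        raise InsufficientDataError("need >= 3 participants for the rate model")
    beta, se, p = _ols(sub["rate"].to_numpy(dtype=float),
                       sub[["uus_total"]].astype(float), "uus_total")
    return ModelResult(model="rate", outcome="hba1c_reduction_rate",
                       visit_month=visit_month, beta=beta, se=se, p=p,
                       n=len(sub))


@dataclass(frozen=True)
class BonferroniThreshold:
    exact: float
    truncated: float
    m: int = field(default=1)


def bonferroni_threshold(alpha: float, m: int) -> BonferroniThreshold:
    """Family-wise threshold alpha/m, also truncated to 3 decimals.

    The truncated form matches the convention of printing the cutoff
    floored at the third decimal (0.05/3 -> .016).
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValidationError(f"m must be >= 1, got {m}")
    exact = alpha / m
    return BonferroniThreshold(exact=exact,
                               truncated=math.floor(exact * 1000) / 1000,
                               m=m)
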