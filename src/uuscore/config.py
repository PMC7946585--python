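"""Simulation scenario configuration.

A :class:`SimulationConfig` fully describes a synthetic cohort: how many
participants, how their daily app engagement is distributed, the baseline
covariate distributions, the true longitudinal effect of the engagement
score on HbA1c, and group-differential loss to follow-up.  Scenarios are
plain YAML documents; three are packaged (``trial_calibrated``,
``trial_calibrated_rate`` and ``null``) and can be loaded by name with
:func:`load_scenario`.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigurationError

#: engagement components (daily-flag counts) in canonical order
COUNT_COMPONENTS = ("smbg", "diet", "exercise")

#: continuous baseline covariates and their serialized column names
CONTINUOUS_COVARIATES = (
    "age", "bmi", "sbp", "dbp", "hba1c_baseline", "total_chol", "tg",
    "hdl", "ldl", "dm_duration", "sdsca_diet", "sdsca_exercise",
    "sdsca_glucose", "sdsca_foot", "ads_total",
)

#: binary baseline covariates ("male" is serialized as the sex column)
BINARY_COVARIATES = (
    "male", "smoker", "drinker", "insulin", "antihypertensive",
    "antidyslipidemic",
)

#: secondary longitudinal outcomes (everything but HbA1c)
SECONDARY_OUTCOMES = (
    "bmi", "sbp", "dbp", "total_chol", "tg", "hdl", "ldl",
    "sdsca_diet", "sdsca_exercise", "sdsca_glucose", "sdsca_foot",
    "ads_total",
)

#: physiological floors applied when sampling continuous covariates
_CLIP_MIN = {
    "age": 20.0, "bmi": 15.0, "sbp": 80.0, "dbp": 45.0,
    "hba1c_baseline": 4.5, "total_chol": 80.0, "tg": 30.0, "hdl": 20.0,
    "ldl": 30.0, "dm_duration": 0.0, "sdsca_diet": 0.0,
    "sdsca_exercise": 0.0, "sdsca_glucose": 0.0, "sdsca_foot": 0.0,
    "ads_total": 7.0,
}

VISIT_MONTHS = (0, 3, 6, 12)
FOLLOWUP_MONTHS = (3, 6, 12)


@dataclass(frozen=True)
class ComponentDist:
    """Distribution of one engagement behaviour.

    ``kind="beta"`` draws a per-participant daily propensity p ~
    Beta(alpha, beta); the day count over D days is then beta-binomial
    (over-dispersed, bounded by D).  ``kind="fixed"`` uses a constant
    propensity ``p`` for every participant — mainly for degenerate test
    scenarios (p=0: never records; p=1: records every day).
    """

    kind: str
    alpha: float = 1.0
    beta: float = 1.0
    p: float = 0.5

    def validate(self, name: str) -> None:
        if self.kind not in ("beta", "fixed"):
            raise ConfigurationError(name, f"unknown kind {self.kind!r}")
        if self.kind == "beta" and (self.alpha <= 0 or self.beta <= 0):
            raise ConfigurationError(name, "beta shape parameters must be > 0")
        if self.kind == "fixed" and not 0.0 <= self.p <= 1.0:
            raise ConfigurationError(name, "fixed propensity must be in [0, 1]")

    def to_dict(self) -> dict:
        if self.kind == "beta":
            return {"kind": "beta", "alpha": self.alpha, "beta": self.beta}
        return {"kind": "fixed", "p": self.p}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ComponentDist":
        return cls(**dict(d))


@dataclass(frozen=True)
class EngagementModel:
    """Per-component engagement distributions plus the message schedule."""

    smbg: ComponentDist
    diet: ComponentDist
    exercise: ComponentDist
    read_prob: ComponentDist

    def validate(self) -> None:
        for name in (*COUNT_COMPONENTS, "read_prob"):
            getattr(self, name).validate(f"engagement.{name}")

    def to_dict(self) -> dict:
        return {name: getattr(self, name).to_dict()
                for name in (*COUNT_COMPONENTS, "read_prob")}

    @classmethod
    def from_dict(cls, d: Mapping) -> "EngagementModel":
        return cls(**{k: ComponentDist.from_dict(v) for k, v in d.items()})


@dataclass(frozen=True)
class CovariateModel:
    """Baseline covariate distributions.

    Continuous covariates are sampled as independent truncated normals
    (physiological floors); binary covariates as Bernoulli proportions.
    Covariates are independent of engagement by design, so adjusted and
    structural regression coefficients coincide.
    """

    continuous: Mapping[str, tuple]  # name -> (mean, sd)
    binary: Mapping[str, float]      # name -> proportion

    def validate(self) -> None:
        for name in CONTINUOUS_COVARIATES:
            if name not in self.continuous:
                raise ConfigurationError(f"covariates.continuous.{name}", "missing")
            mean, sd = self.continuous[name]
            if sd < 0:
                raise ConfigurationError(
                    f"covariates.continuous.{name}", f"sd must be >= 0, got {sd}")
        for name in BINARY_COVARIATES:
            if name not in self.binary:
                raise ConfigurationError(f"covariates.binary.{name}", "missing")
            p = self.binary[name]
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"covariates.binary.{name}", f"proportion must be in [0, 1], got {p}")

    def to_dict(self) -> dict:
        return {
            "continuous": {k: {"mean": float(m), "sd": float(s)}
                           for k, (m, s) in self.continuous.items()},
            "binary": {k: float(v) for k, v in self.binary.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CovariateModel":
        cont = {k: (v["mean"], v["sd"]) for k, v in d["continuous"].items()}
        return cls(continuous=cont, binary=dict(d["binary"]))


@dataclass(frozen=True)
class TrueEffects:
    """Ground-truth longitudinal generative model for HbA1c.

    On the ``change`` scale, the HbA1c change at month M is

        delta_M = intercept_M + beta_M * UUS
                  + gamma * (baseline - cohort mean baseline) + eps_M,

    with eps_M ~ N(0, residual_sd_M).  On the ``rate`` scale the same
    linear predictor generates the *percent reduction rate*, and the
    absolute change is baseline * rate / 100 — so a simple regression of
    the reduction rate on UUS recovers beta_M exactly.

    Units: ``change`` betas are % HbA1c per UUS point; ``rate`` betas are
    percent-of-baseline per UUS point.
    """

    beta_uus_by_visit: Mapping[int, float]
    residual_sd_by_visit: Mapping[int, float]
    intercept_by_visit: Mapping[int, float] = field(default_factory=dict)
    gamma_baseline_hba1c: float = 0.0
    secondary_effects: Mapping[str, float] = field(default_factory=dict)
    secondary_sd: Mapping[str, float] = field(default_factory=dict)
    scale: str = "change"

    def validate(self) -> None:
        if self.scale not in ("change", "rate"):
            raise ConfigurationError("effects.scale", f"unknown scale {self.scale!r}")
        for month in self.beta_uus_by_visit:
            if month not in self.residual_sd_by_visit:
                raise ConfigurationError(
                    f"effects.residual_sd_by_visit.{month}",
                    "every visit with a UUS effect needs a residual SD")
        for month, sd in self.residual_sd_by_visit.items():
            if sd < 0:
                raise ConfigurationError(
                    f"effects.residual_sd_by_visit.{month}", f"sd must be >= 0, got {sd}")
        for name in self.secondary_effects:
            if name not in SECONDARY_OUTCOMES:
                raise ConfigurationError(
                    f"effects.secondary_effects.{name}", "unknown outcome")

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "beta_uus_by_visit": {int(k): float(v) for k, v in self.beta_uus_by_visit.items()},
            "intercept_by_visit": {int(k): float(v) for k, v in self.intercept_by_visit.items()},
            "gamma_baseline_hba1c": float(self.gamma_baseline_hba1c),
            "residual_sd_by_visit": {int(k): float(v) for k, v in self.residual_sd_by_visit.items()},
            "secondary_effects": dict(self.secondary_effects),
            "secondary_sd": dict(self.secondary_sd),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrueEffects":
        d = dict(d)
        for key in ("beta_uus_by_visit", "intercept_by_visit", "residual_sd_by_visit"):
            if key in d:
                d[key] = {int(k): float(v) for k, v in d[key].items()}
        return cls(**d)


@dataclass(frozen=True)
class DropoutModel:
    """Month-12 loss-to-follow-up probabilities by engagement group.

    Dropout is missing-completely-at-random within group; months 0/3/6
    are always observed.
    """

    low: float
    high: float

    def validate(self) -> None:
        for name in ("low", "high"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"dropout.{name}", f"probability must be in [0, 1], got {p}")

    def to_dict(self) -> dict:
        return {"low": float(self.low), "high": float(self.high)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "DropoutModel":
        return cls(**dict(d))


@dataclass(frozen=True)
class SimulationConfig:
    """Complete generative scenario for one synthetic cohort."""

    n_participants: int
    engagement: EngagementModel
    covariates: CovariateModel
    effects: TrueEffects
    dropout: DropoutModel
    study_days: int = 91
    messages_per_week: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 4:
            raise ConfigurationError("n_participants", "need at least 4 participants")
        if self.study_days < 1:
            raise ConfigurationError("study_days", "must be a positive integer")
        if self.messages_per_week < 1:
            raise ConfigurationError("messages_per_week", "must be a positive integer")
        self.engagement.validate()
        self.covariates.validate()
        self.effects.validate()
        self.dropout.validate()

    def replace(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given top-level fields replaced."""
        import dataclasses
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "n_participants": int(self.n_participants),
            "study_days": int(self.study_days),
            "messages_per_week": int(self.messages_per_week),
            "seed": int(self.seed),
            "engagement": self.engagement.to_dict(),
            "covariates": self.covariates.to_dict(),
            "effects": self.effects.to_dict(),
            "dropout": self.dropout.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = copy.deepcopy(dict(d))
        d["engagement"] = EngagementModel.from_dict(d["engagement"])
        d["covariates"] = CovariateModel.from_dict(d["covariates"])
        d["effects"] = TrueEffects.from_dict(d["effects"])
        d["dropout"] = DropoutModel.from_dict(d["dropout"])
        config = cls(**d)
        config.validate()
        return config

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def packaged_scenarios() -> list[str]:
    """Names of the scenarios shipped with the package."""
    root = resources.files("uuscore") / "scenarios"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_scenario(name_or_path: str | Path) -> SimulationConfig:
    """Load a scenario by packaged name (e.g. ``trial_calibrated``) or path."""
    path = Path(name_or_path)
    if path.suffix in (".yaml", ".yml") and path.exists():
        return SimulationConfig.from_yaml(path)
    ref = resources.files("uuscore") / "scenarios" / f"{name_or_path}.yaml"
    if not ref.is_file():
        raise ConfigurationError(
            "scenario",
            f"{name_or_path!r} is neither a file nor a packaged scenario "
            f"(available: {', '.join(packaged_scenarios())})")
    return SimulationConfig.from_dict(yaml.safe_load(ref.read_text()))
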