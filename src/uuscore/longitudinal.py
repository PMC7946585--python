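"""Longitudinal preparation: LOCF imputation, changes from baseline,
and the HbA1c reduction-rate statistic.

LOCF (last observation carried forward) replaces a missing post-baseline
value with the participant's most recent earlier observed value of the
same outcome.  It is applied to any missing follow-up visit, requires an
observed baseline, never alters observed values, and is idempotent.
Questionnaire scales (SDSCA subscales, ADS) are structurally absent at
month 3 — they were not administered — and are deliberately not imputed
there.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import VISIT_MONTHS
from .errors import MissingBaselineError, ValidationError
from .io import VISIT_OUTCOMES
from .simulate import QUESTIONNAIRE_OUTCOMES


def _pivot(visits: pd.DataFrame, outcome: str) -> pd.DataFrame:
    return visits.pivot(index="participant_id", columns="visit_month",
                        values=outcome)


def locf_impute(visits: pd.DataFrame,
                outcomes=VISIT_OUTCOMES) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Carry the last observed value forward into missing follow-ups.

    Returns ``(filled, imputed)``: a copy of ``visits`` with missing
    post-baseline outcome values replaced, and a same-shape boolean
    frame marking which cells were imputed.  Raises
    :class:`MissingBaselineError` if an imputation is needed but no
    earlier observed value exists (ultimately: a missing baseline).
    """
    filled = visits.sort_values(["participant_id", "visit_month"],
                                ignore_index=True)
    imputed = pd.DataFrame(False, index=filled.index, columns=list(outcomes))
    for outcome in outcomes:
        structural = ((filled["visit_month"] == 3)
                      & (outcome in QUESTIONNAIRE_OUTCOMES))
        values = filled[outcome].copy()
        carried = values.groupby(filled["participant_id"]).ffill()
        # structurally absent cells stay absent and never propagate issues
        fill_mask = values.isna() & carried.notna() & ~structural
        still_missing = values.isna() & carried.isna() & ~structural
        post = filled["visit_month"] > 0
        if (still_missing & post).any():
            bad = filled.loc[still_missing & post, "participant_id"].iloc[0]
            raise MissingBaselineError(
                f"participant {bad!r} has no earlier observed {outcome!r} "
                "to carry forward (missing baseline)")
        filled.loc[fill_mask, outcome] = carried[fill_mask]
        imputed[outcome] = fill_mask
    return filled, imputed


def change_from_baseline(visits: pd.DataFrame, outcome: str,
                         imputed: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-participant change from baseline at each follow-up month.

    Returns a long table (participant_id, visit_month, outcome, delta,
    imputed); ``delta`` is follow-up minus baseline in the outcome's
    units.  ``imputed`` flags (from :func:`locf_impute`) are propagated
    when given.  Missing values propagate to missing deltas.
    """
    if outcome not in visits.columns:
        raise ValidationError(f"unknown outcome column {outcome!r}")
    wide = _pivot(visits, outcome)
    if 0 not in wide.columns:
        raise MissingBaselineError(f"no month-0 visit for outcome {outcome!r}")
    flag = (pd.DataFrame(False, index=visits.index,
                         columns=[outcome]) if imputed is None else imputed)
    flag_wide = visits[["participant_id", "visit_month"]].assign(
        f=flag[outcome].to_numpy()).pivot(
        index="participant_id", columns="visit_month", values="f")
    records = []
    for month in [m for m in VISIT_MONTHS if m != 0 and m in wide.columns]:
        records.append(pd.DataFrame({
            "participant_id": wide.index,
            "visit_month": month,
            "outcome": outcome,
            "delta": (wide[month] - wide[0]).to_numpy(),
            "imputed": flag_wide[month].fillna(False).to_numpy(dtype=bool),
        }))
    return pd.concat(records, ignore_index=True)


def reduction_rate(baseline_hba1c, followup_hba1c):
    """Percent HbA1c reduction rate: 100·(follow-up − baseline)/baseline.

    Signed: negative values indicate improvement.  Accepts scalars or
    arrays; baseline must be strictly positive.
    """
    b = np.asarray(baseline_hba1c, dtype=float)
    f = np.asarray(followup_hba1c, dtype=float)
    if np.any(b <= 0):
        raise ValidationError("baseline HbA1c must be > 0")
    out = 100.0 * (f - b) / b
    return float(out) if out.ndim == 0 else out
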