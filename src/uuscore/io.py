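"""Tabular I/O with strict schema validation.

Three CSV schemas travel between pipeline stages:

* ``logs.csv`` — one row per participant per study day with boolean
  record flags (serialized 0/1) and message counts;
* ``baseline.csv`` — one row per participant with demographics, vitals,
  labs, medication flags and questionnaire totals;
* ``visits.csv`` — one row per participant per visit month (0/3/6/12)
  with the longitudinal outcomes; missing values are empty fields.

All files are UTF-8, comma-separated, header required.  Readers reject
rows that violate schema invariants with row-numbered diagnostics.
Write→read is the identity on all three schemas.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SECONDARY_OUTCOMES, VISIT_MONTHS
from .errors import SchemaError, ValidationError

logger = logging.getLogger("uuscore")

LOG_COLUMNS = (
    "participant_id", "day", "smbg_recorded", "diet_recorded",
    "exercise_recorded", "messages_sent", "messages_read",
)
_LOG_BOOL = ("smbg_recorded", "diet_recorded", "exercise_recorded")

BASELINE_COLUMNS = (
    "participant_id", "age", "sex", "bmi", "sbp", "dbp", "hba1c_baseline",
    "total_chol", "tg", "hdl", "ldl", "smoker", "drinker", "dm_duration",
    "insulin", "antihypertensive", "antidyslipidemic", "sdsca_diet",
    "sdsca_exercise", "sdsca_glucose", "sdsca_foot", "ads_total",
)
_BASELINE_BOOL = ("smoker", "drinker", "insulin", "antihypertensive",
                  "antidyslipidemic")

#: longitudinal outcome columns, HbA1c first
VISIT_OUTCOMES = ("hba1c", *SECONDARY_OUTCOMES)

VISIT_COLUMNS = ("participant_id", "visit_month", *VISIT_OUTCOMES, "observed")


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def _fail_rows(mask: pd.Series, path, field: str, reason: str) -> None:
    if mask.any():
        rows = (np.flatnonzero(mask.to_numpy()) + 2)[:5]  # 1-based + header
        raise ValidationError(
            f"{path}: field {field!r} {reason} "
            f"(rows {', '.join(map(str, rows))}{'…' if mask.sum() > 5 else ''})")


def read_logs(path: str | Path, study_days: int = 91) -> pd.DataFrame:
    """Read and validate a daily engagement log table."""
    df = pd.read_csv(path)
    _require_columns(df, LOG_COLUMNS, path)
    df = df[list(LOG_COLUMNS)]
    for col in ("day", "messages_sent", "messages_read"):
        _fail_rows(df[col].isna() | (df[col] % 1 != 0), path, col,
                   "must be an integer")
        df[col] = df[col].astype(np.int64)
    for col in _LOG_BOOL:
        _fail_rows(~df[col].isin([0, 1, True, False]), path, col, "must be 0/1")
        df[col] = df[col].astype(bool)
    _fail_rows(~df["day"].between(1, study_days), path, "day",
               f"must be in 1..{study_days}")
    _fail_rows(df["messages_sent"] < 0, path, "messages_sent", "must be >= 0")
    _fail_rows(df["messages_read"] < 0, path, "messages_read", "must be >= 0")
    _fail_rows(df["messages_read"] > df["messages_sent"], path,
               "messages_read", "exceeds messages_sent")
    dup = df.duplicated(subset=["participant_id", "day"])
    _fail_rows(dup, path, "participant_id/day", "duplicated")
    logger.info("read %d log rows for %d participants from %s",
                len(df), df["participant_id"].nunique(), path)
    return df


def read_baseline(path: str | Path) -> pd.DataFrame:
    """Read and validate the baseline covariate table."""
    df = pd.read_csv(path)
    _require_columns(df, BASELINE_COLUMNS, path)
    df = df[list(BASELINE_COLUMNS)]
    _fail_rows(~df["sex"].isin(["male", "female"]), path, "sex",
               "must be 'male' or 'female'")
    for col in _BASELINE_BOOL:
        _fail_rows(~df[col].isin([0, 1, True, False]), path, col, "must be 0/1")
        df[col] = df[col].astype(bool)
    _fail_rows(df["hba1c_baseline"] <= 0, path, "hba1c_baseline", "must be > 0")
    for col in ("age", "dm_duration"):
        _fail_rows(df[col] < 0, path, col, "must be >= 0")
    dup = df.duplicated(subset=["participant_id"])
    _fail_rows(dup, path, "participant_id", "duplicated")
    logger.info("read baseline covariates for %d participants from %s",
                len(df), path)
    return df


def read_visits(path: str | Path) -> pd.DataFrame:
    """Read and validate the longitudinal visit table.

    Per-field missingness is allowed (empty cells); every participant
    must have an observed month-0 record with a non-missing HbA1c.
    """
    df = pd.read_csv(path)
    _require_columns(df, VISIT_COLUMNS, path)
    df = df[list(VISIT_COLUMNS)]
    _fail_rows(~df["visit_month"].isin(VISIT_MONTHS), path, "visit_month",
               f"must be one of {VISIT_MONTHS}")
    _fail_rows(~df["observed"].isin([0, 1, True, False]), path, "observed",
               "must be 0/1")
    df["visit_month"] = df["visit_month"].astype(np.int64)
    df["observed"] = df["observed"].astype(bool)
    for col in VISIT_OUTCOMES:
        df[col] = df[col].astype(float)
    dup = df.duplicated(subset=["participant_id", "visit_month"])
    _fail_rows(dup, path, "participant_id/visit_month", "duplicated")
    month0 = df[df["visit_month"] == 0]
    have_baseline = set(month0.loc[month0["observed"] & month0["hba1c"].notna(),
                                   "participant_id"])
    missing = sorted(set(df["participant_id"]) - have_baseline)
    if missing:
        raise ValidationError(
            f"{path}: participants without an observed month-0 HbA1c: "
            f"{missing[:5]}{'…' if len(missing) > 5 else ''}")
    logger.info("read %d visit rows for %d participants from %s",
                len(df), df["participant_id"].nunique(), path)
    return df


def _write(df: pd.DataFrame, path: str | Path, bool_cols=()) -> None:
    out = df.copy()
    for col in out.columns:
        if col in bool_cols or out[col].dtype == bool:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False)


def write_logs(df: pd.DataFrame, path: str | Path) -> None:
    _write(df[list(LOG_COLUMNS)], path)


def write_baseline(df: pd.DataFrame, path: str | Path) -> None:
    _write(df[list(BASELINE_COLUMNS)], path)


def write_visits(df: pd.DataFrame, path: str | Path) -> None:
    _write(df[list(VISIT_COLUMNS)], path)
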