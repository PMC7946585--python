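"""User utility score (UUS): tertile-based composite engagement scoring.

The UUS condenses the first three months of a participant's mobile-app
engagement into a single 0–8 integer.  Four components are summarized
over the scoring window — days with a self-monitored blood glucose
(SMBG) entry, days with a dietary record, days with an exercise record,
and the percentage of coaching messages read.  Each component is cut at
the cohort's empirical 1/3 and 2/3 quantiles (tertiles T1/T2/T3, scored
0/1/2) and the four scores are summed.  The cohort is then split into a
low- and a high-engagement group at the median UUS.

Conventions (fixed across the package):

* Quantiles use the inverted-ECDF (nearest-lower-rank) definition, so
  integer day counts produce integer cut points.
* Ties at a cut point go to the *lower* tertile (membership is ``<=``),
  matching inclusive tertile ranges such as 0–33 / 34–75 / 76–91 days.
* Participants who were sent no messages get a read rate of 0 and are
  flagged (``read_rate_undefined``).
* The median split sends ties at the threshold to the low group; a
  non-integer median is floored, so a median of 4.5 yields groups
  UUS 0–4 and UUS 5–8.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateSplitError, InsufficientDataError, ValidationError

#: the four scored components, in canonical order
COMPONENTS = ("smbg_days", "diet_days", "exercise_days", "read_rate")

#: maximum attainable total (four components scored 0-2)
UUS_MAX = 8


@dataclass(frozen=True)
class TertileCuts:
    """Cohort-derived tertile boundaries for one component.

    ``value <= cut1`` scores 0, ``cut1 < value <= cut2`` scores 1 and
    ``value > cut2`` scores 2.
    """

    component: str
    cut1: float
    cut2: float

    def __post_init__(self):
        if self.cut1 > self.cut2:
            raise ValueError(f"cut1 must be <= cut2, got ({self.cut1}, {self.cut2})")


def summarize_engagement(logs: pd.DataFrame, window_days: int = 91) -> pd.DataFrame:
    """Aggregate daily logs into per-participant engagement summaries.

    Parameters
    ----------
    logs
        Daily log table (one row per participant per day) with boolean
        record flags and message counts.
    window_days
        Scoring window: only days ``1..window_days`` contribute.

    Returns
    -------
    DataFrame with one row per participant: day counts per component,
    ``read_rate`` in percent, and a ``read_rate_undefined`` flag for
    participants with no messages sent in the window.
    """
    if logs.empty:
        raise InsufficientDataError("no participants in the log table")
    if window_days < 1:
        raise ValidationError(f"window_days must be >= 1, got {window_days}")
    window = logs[logs["day"].between(1, window_days)]
    grouped = window.groupby("participant_id", sort=True)
    out = grouped.agg(
        smbg_days=("smbg_recorded", "sum"),
        diet_days=("diet_recorded", "sum"),
        exercise_days=("exercise_recorded", "sum"),
        sent=("messages_sent", "sum"),
        read=("messages_read", "sum"),
    ).reset_index()
    undefined = out["sent"] == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = 100.0 * out["read"] / out["sent"]
    out["read_rate"] = rate.where(~undefined, 0.0)
    out["read_rate_undefined"] = undefined
    for col in ("smbg_days", "diet_days", "exercise_days"):
        out[col] = out[col].astype(np.int64)
    return out.drop(columns=["sent", "read"])


def compute_tertile_cuts(values, component: str) -> TertileCuts:
    """Empirical tertile boundaries of a component, inverted-ECDF convention.

    Requires at least 3 observations.  If all values are identical the
    cuts are degenerate (cut1 == cut2 == that value, every score 0) and
    a warning is emitted.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise InsufficientDataError(
            f"need >= 3 values to form tertiles for {component!r}, got {arr.size}")
    if np.isnan(arr).any():
        raise ValidationError(f"missing values in component {component!r}")
    cut1, cut2 = np.quantile(arr, [1 / 3, 2 / 3], method="inverted_cdf")
    if arr.min() == arr.max():
        warnings.warn(
            f"all {component!r} values identical ({arr.min()}): "
            "degenerate cuts, every participant scores 0",
            stacklevel=2)
    return TertileCuts(component=component, cut1=float(cut1), cut2=float(cut2))


def score_component(value: float, cuts: TertileCuts) -> int:
    """Map a raw component value to its tertile score 0/1/2 (ties go low)."""
    if value <= cuts.cut1:
        return 0
    if value <= cuts.cut2:
        return 1
    return 2


def compute_uus(summaries: pd.DataFrame,
                cuts: dict[str, TertileCuts]) -> pd.DataFrame:
    """Score every participant on all four components and sum to the UUS.

    ``cuts`` maps each component name in :data:`COMPONENTS` to its
    :class:`TertileCuts`.  Returns a table with per-component scores,
    ``uus_total`` (0–8) and an unset ``group`` column.
    """
    missing = [c for c in COMPONENTS if c not in cuts]
    if missing:
        raise ValidationError(f"missing tertile cuts for components: {missing}")
    out = summaries[["participant_id", *COMPONENTS]].copy()
    total = np.zeros(len(out), dtype=np.int64)
    for comp in COMPONENTS:
        c = cuts[comp]
        vals = out[comp].to_numpy(dtype=float)
        scores = np.where(vals <= c.cut1, 0, np.where(vals <= c.cut2, 1, 2))
        out[f"{comp}_score"] = scores
        total += scores
    out["uus_total"] = total
    out["group"] = pd.Series(pd.NA, index=out.index, dtype="string")
    return out


def split_by_median(uus: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Split the cohort into low/high groups at the median UUS.

    The threshold is the cohort median, floored when non-integer; the
    low group is ``uus_total <= threshold``.  Returns the labelled table
    and the threshold.  Raises :class:`DegenerateSplitError` when every
    participant has the same score.
    """
    if len(uus) < 2:
        raise InsufficientDataError("need >= 2 participants for a median split")
    totals = uus["uus_total"].to_numpy()
    if totals.min() == totals.max():
        raise DegenerateSplitError(
            f"all participants share UUS {totals[0]}; no median split exists")
    threshold = int(np.floor(np.median(totals)))
    out = uus.copy()
    out["group"] = np.where(out["uus_total"] <= threshold, "low", "high")
    out["group"] = out["group"].astype("string")
    return out, threshold


def group_labels(threshold: int) -> dict[str, str]:
    """Human-readable range labels for the two groups, e.g. ``UUS:0-4``."""
    return {"low": f"UUS:0-{threshold}", "high": f"UUS:{threshold + 1}-{UUS_MAX}"}
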