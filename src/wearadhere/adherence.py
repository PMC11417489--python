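"""Adherence scores, group labels, trajectories and data return.

Group cut points (config-overridable): long-term adherence >= 95% is
*optimal*, <= 75% is *low*, otherwise *moderate*; daily adherence uses
90% for the optimal bound.  The bounds are closed at both the optimal
and low cut points ("95% or higher", "75% or lower"), with the
moderate band the open interval between them.

The mean-daily-adherence denominator excludes changeover and
logistics-loss days as well as zero-wear days: a cohort whose median
daily adherence (fraction of the day worn on days the device is worn
at all) far exceeds its long-term adherence is only arithmetically
possible under this convention.  The alternative (all expected days)
is available via ``daily_denominator="expected"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .day_accounting import expected_days as _expected_days
from .types import AccountingError, AdherenceSummary, DayClass, DomainError

__all__ = [
    "long_term_adherence",
    "daily_adherence",
    "classify_groups",
    "period_trajectory",
    "data_return",
    "summarize_participant",
    "summarize_cohort",
    "cohort_summary",
    "group_share_pct",
    "GroupThresholds",
]


@dataclass(frozen=True)
class GroupThresholds:
    optimal_long_term: float = 0.95
    optimal_daily: float = 0.90
    low: float = 0.75


def long_term_adherence(valid_days: int, expected_days: int) -> float:
    """Valid days over expected days; NaN (flagged) when expected is 0."""
    if valid_days < 0:
        raise AccountingError(f"negative valid_days: {valid_days}")
    if valid_days > expected_days:
        raise AccountingError(
            f"valid_days {valid_days} exceeds expected_days {expected_days}"
        )
    if expected_days == 0:
        return float("nan")
    return valid_days / expected_days


def data_return(valid_days: int, protocol_days: int) -> float:
    """Valid days over the theoretical protocol maximum for one participant."""
    if not 0 <= valid_days <= protocol_days:
        raise AccountingError(
            f"valid_days {valid_days} outside [0, {protocol_days}]"
        )
    return valid_days / protocol_days


def _qualifying_mask(day_records: pd.DataFrame, denominator: str) -> pd.Series:
    not_logistics = ~day_records["day_class"].isin(
        [DayClass.CHANGEOVER.value, DayClass.NPC_NONWEAR.value]
    )
    if denominator == "expected":
        return not_logistics
    return not_logistics & (day_records["wear_hours"] > 0.0)


def daily_adherence(
    day_records: pd.DataFrame, denominator: str = "positive_wear"
) -> float:
    """Mean of wear_hours/24 over qualifying days; NaN if none qualify."""
    mask = _qualifying_mask(day_records, denominator)
    if not mask.any():
        return float("nan")
    return float((day_records.loc[mask, "wear_hours"] / 24.0).mean())


def classify_groups(
    long_term: float,
    daily: float,
    thresholds: GroupThresholds = GroupThresholds(),
) -> Tuple[str, str]:
    """Map (long-term, daily) adherence fractions to group labels.

    Undefined (NaN) adherence classifies as ``low``: a participant with
    no expected days withdrew outright.
    """

    def _one(value: float, optimal_cut: float) -> str:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return "low"
        if not 0.0 <= value <= 1.0:
            raise DomainError(f"adherence fraction outside [0, 1]: {value}")
        if value >= optimal_cut:
            return "optimal"
        if value <= thresholds.low:
            return "low"
        return "moderate"

    return _one(long_term, thresholds.optimal_long_term), _one(
        daily, thresholds.optimal_daily
    )


def period_trajectory(
    day_records: pd.DataFrame,
    period_edges: Tuple[int, int] = (60, 120),
    protocol_days: int = 182,
    thresholds: GroupThresholds = GroupThresholds(),
) -> Tuple[Tuple[float, float, float], Tuple[str, str, str]]:
    """Long-term adherence and group per study period (months 1-2/3-4/5-6).

    Default edges split [1, 182] into [1, 60], [61, 120], [121, 182]
    (documented 60/60/62 split; "six months" has no exact thirds).  A
    window consisting entirely of post-withdrawal days is labelled
    ``dropped_out``.
    """
    e1, e2 = period_edges
    windows = [(1, e1), (e1 + 1, e2), (e2 + 1, protocol_days)]
    adh: List[float] = []
    grp: List[str] = []
    for lo, hi in windows:
        win = day_records[(day_records["study_day"] >= lo) & (day_records["study_day"] <= hi)]
        if len(win) and (win["day_class"] == DayClass.POST_WITHDRAWAL.value).all():
            adh.append(float("nan"))
            grp.append("dropped_out")
            continue
        counts = win["day_class"].value_counts()
        denom = len(win) - int(counts.get(DayClass.NPC_NONWEAR.value, 0)) - int(
            counts.get(DayClass.CHANGEOVER.value, 0)
        )
        valid = int(counts.get(DayClass.VALID.value, 0))
        a = long_term_adherence(valid, denom)
        adh.append(a)
        grp.append(classify_groups(a, a, thresholds)[0])
    return tuple(adh), tuple(grp)


def summarize_participant(
    day_records: pd.DataFrame,
    protocol_days: int = 182,
    period_edges: Tuple[int, int] = (60, 120),
    thresholds: GroupThresholds = GroupThresholds(),
    count_post_withdrawal: bool = True,
    daily_denominator: str = "positive_wear",
) -> AdherenceSummary:
    """All adherence quantities for one participant's complete day set."""
    pid = str(day_records["participant_id"].iloc[0])
    exp = _expected_days(day_records, protocol_days, count_post_withdrawal)
    valid = int((day_records["day_class"] == DayClass.VALID.value).sum())
    lt = long_term_adherence(valid, exp)
    da = daily_adherence(day_records, daily_denominator)
    lt_group, daily_group = classify_groups(lt, da, thresholds)
    periods, period_groups = period_trajectory(
        day_records, period_edges, protocol_days, thresholds
    )
    return AdherenceSummary(
        participant_id=pid,
        valid_days=valid,
        expected_days=exp,
        long_term_adherence=lt,
        mean_daily_adherence=da,
        lt_group=lt_group,
        daily_group=daily_group,
        period_lt_adherence=periods,
        period_lt_groups=period_groups,
        data_return=data_return(valid, protocol_days),
    )


def summarize_cohort(
    day_records: pd.DataFrame,
    protocol_days: int = 182,
    period_edges: Tuple[int, int] = (60, 120),
    thresholds: GroupThresholds = GroupThresholds(),
    count_post_withdrawal: bool = True,
    daily_denominator: str = "positive_wear",
) -> pd.DataFrame:
    """Per-participant :func:`summarize_participant`, as a flat table."""
    rows = []
    for _, grp in day_records.groupby("participant_id", sort=True):
        s = summarize_participant(
            grp, protocol_days, period_edges, thresholds,
            count_post_withdrawal, daily_denominator,
        )
        rows.append(
            {
                "participant_id": s.participant_id,
                "valid_days": s.valid_days,
                "expected_days": s.expected_days,
                "long_term_adherence": s.long_term_adherence,
                "mean_daily_adherence": s.mean_daily_adherence,
                "lt_group": s.lt_group,
                "daily_group": s.daily_group,
                "period1_lt": s.period_lt_adherence[0],
                "period2_lt": s.period_lt_adherence[1],
                "period3_lt": s.period_lt_adherence[2],
                "period1_group": s.period_lt_groups[0],
                "period2_group": s.period_lt_groups[1],
                "period3_group": s.period_lt_groups[2],
                "data_return": s.data_return,
            }
        )
    return pd.DataFrame(rows)


def group_share_pct(count: int, total: int, decimals: int = 1) -> float:
    """Percentage share of a group, rounded as reported (one decimal)."""
    if total <= 0:
        raise DomainError("total must be positive")
    return round(100.0 * count / total, decimals)


def _median_iqr(x: pd.Series) -> Tuple[float, float, float]:
    x = x.dropna()
    if x.empty:
        return float("nan"), float("nan"), float("nan")
    return float(x.median()), float(x.quantile(0.25)), float(x.quantile(0.75))


def cohort_summary(
    summaries: pd.DataFrame,
    profiles: Optional[pd.DataFrame] = None,
    protocol_days: int = 182,
) -> dict:
    """Cohort-level report: medians/IQRs, group counts, splits.

    Undefined adherences (NaN) are excluded from medians but counted in
    the group tables (as ``low``, the label :func:`classify_groups`
    assigns them).
    """
    if summaries.empty:
        raise AccountingError("empty cohort")
    n = len(summaries)
    lt_med, lt_lo, lt_hi = _median_iqr(summaries["long_term_adherence"])
    da_med, da_lo, da_hi = _median_iqr(summaries["mean_daily_adherence"])
    dr_med, dr_lo, dr_hi = _median_iqr(summaries["data_return"])
    days_med, days_lo, days_hi = _median_iqr(summaries["valid_days"].astype(float))

    def _counts(col: str) -> pd.DataFrame:
        counts = summaries[col].value_counts().reindex(
            ["optimal", "moderate", "low"], fill_value=0
        )
        return pd.DataFrame(
            {
                "group": counts.index,
                "count": counts.to_numpy(),
                "pct": [group_share_pct(int(c), n) for c in counts.to_numpy()],
            }
        )

    traj = (
        summaries.groupby(["period1_group", "period2_group", "period3_group"])
        .size()
        .rename("count")
        .reset_index()
        .sort_values("count", ascending=False, ignore_index=True)
    )

    out = {
        "n_participants": n,
        "theoretical_max_days": protocol_days * n,
        "long_term_adherence_median_iqr": (lt_med, lt_lo, lt_hi),
        "daily_adherence_median_iqr": (da_med, da_lo, da_hi),
        "data_return_median_iqr": (dr_med, dr_lo, dr_hi),
        "valid_days_median_iqr": (days_med, days_lo, days_hi),
        "total_valid_days": int(summaries["valid_days"].sum()),
        "lt_group_counts": _counts("lt_group"),
        "daily_group_counts": _counts("daily_group"),
        "trajectories": traj,
    }
    if profiles is not None:
        merged = summaries.merge(profiles, on="participant_id")
        for key in ("centre", "schedule_type"):
            out[f"lt_by_{key}"] = (
                merged.groupby(key)["long_term_adherence"]
                .median()
                .rename("median_lt")
                .reset_index()
            )
        out["schedule_by_group"] = (
            merged.groupby(["schedule_type", "lt_group"]).size().rename("count").reset_index()
        )
    return out
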