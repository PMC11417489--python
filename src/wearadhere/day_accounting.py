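"""Day taxonomy and expected-day accounting.

Every protocol day belongs to exactly one class:

========================  ====================================================
VALID                     wear time at or above the valid-day threshold (22 h)
PC_NONWEAR                participant-controlled non-wear (below threshold)
NPC_NONWEAR               lost to logistics (damaged/lost/delayed device...)
CHANGEOVER                device-swap day, systemic loss inherent to protocol
POST_WITHDRAWAL           on/after the participant's withdrawal day
========================  ====================================================

Expected days = protocol days minus NPC_NONWEAR minus CHANGEOVER.  By
default POST_WITHDRAWAL days stay in the expected-day denominator
(withdrawal counts against adherence); a switch inverts this.
Precedence when classes compete: CHANGEOVER > NPC_NONWEAR >
POST_WITHDRAWAL > wear-based, because logistics states are
observer-verified while wear-based classes are residual.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .types import AccountingError, DayClass, DeploymentSchedule, DomainError

__all__ = ["classify_day", "expected_days", "build_day_records", "DEFAULT_VALID_THRESHOLD"]

DEFAULT_VALID_THRESHOLD = 22.0


def classify_day(
    wear_hours: float,
    study_day: int,
    schedule: DeploymentSchedule,
    valid_threshold_hours: float = DEFAULT_VALID_THRESHOLD,
) -> DayClass:
    """Assign one protocol day to its class (precedence order above)."""
    if not 0.0 <= wear_hours <= 24.0:
        raise DomainError(f"wear_hours outside [0, 24]: {wear_hours}")
    if study_day in schedule.changeover_days:
        return DayClass.CHANGEOVER
    if study_day in schedule.npc_nonwear_days:
        return DayClass.NPC_NONWEAR
    if schedule.withdrawal_day is not None and study_day >= schedule.withdrawal_day:
        return DayClass.POST_WITHDRAWAL
    if wear_hours >= valid_threshold_hours:
        return DayClass.VALID
    return DayClass.PC_NONWEAR


def expected_days(
    day_records: pd.DataFrame,
    protocol_days: int,
    count_post_withdrawal: bool = True,
) -> int:
    """Expected wear days for one participant's complete record set.

    Raises :class:`AccountingError` unless there is exactly one record
    per study day 1..protocol_days.
    """
    if len(day_records) != protocol_days or set(day_records["study_day"]) != set(
        range(1, protocol_days + 1)
    ):
        raise AccountingError(
            f"incomplete day records: {len(day_records)} rows for "
            f"{protocol_days} protocol days"
        )
    counts = day_records["day_class"].value_counts()
    out = (
        protocol_days
        - int(counts.get(DayClass.NPC_NONWEAR.value, 0))
        - int(counts.get(DayClass.CHANGEOVER.value, 0))
    )
    if not count_post_withdrawal:
        out -= int(counts.get(DayClass.POST_WITHDRAWAL.value, 0))
    return out


def build_day_records(
    day_wear: pd.DataFrame,
    schedules,
    valid_threshold_hours: float = DEFAULT_VALID_THRESHOLD,
    protocol_days: Optional[int] = None,
) -> pd.DataFrame:
    """Classify every (participant, study day) row of a wear-hour table.

    Parameters
    ----------
    day_wear
        Columns ``participant_id, study_day, date, wear_hours``.
    schedules
        Iterable of :class:`DeploymentSchedule`, one per participant.

    Returns the same frame with a ``day_class`` column appended.
    """
    sched = {s.participant_id: s for s in schedules}
    missing = set(day_wear["participant_id"].unique()) - set(sched)
    if missing:
        raise AccountingError(f"no deployment schedule for: {sorted(missing)[:5]}")
    if ((day_wear["wear_hours"] < 0) | (day_wear["wear_hours"] > 24)).any():
        bad = day_wear.loc[
            (day_wear["wear_hours"] < 0) | (day_wear["wear_hours"] > 24)
        ].iloc[0]
        raise DomainError(
            f"wear_hours outside [0, 24] for {bad['participant_id']} "
            f"day {bad['study_day']}: {bad['wear_hours']}"
        )

    out = day_wear.copy()
    classes = []
    for pid, grp in out.groupby("participant_id", sort=False):
        s = sched[pid]
        days = grp["study_day"].to_numpy()
        wear = grp["wear_hours"].to_numpy()
        cls = []
        for d, w in zip(days, wear):
            cls.append(classify_day(float(w), int(d), s, valid_threshold_hours).value)
        classes.append(pd.Series(cls, index=grp.index))
    out["day_class"] = pd.concat(classes).sort_index()
    if protocol_days is not None:
        sizes = out.groupby("participant_id")["study_day"].nunique()
        short = sizes[sizes != protocol_days]
        if len(short):
            raise AccountingError(
                f"participants without a complete day set: {list(short.index[:5])}"
            )
    return out
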