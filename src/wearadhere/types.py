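"""Shared domain types for wear-time adherence analysis.

The vocabulary follows the actigraphy-adherence literature: a *valid day*
is a 24 h civil day with at least a threshold number of worn hours
(default 22 h), *long-term adherence* is valid days over expected days,
*expected days* are protocol days minus days lost to logistics
(non-participant-controlled non-wear) and device changeovers, and
*data return* is valid days over the theoretical protocol maximum.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Mapping, Optional, Tuple


class DayClass(str, enum.Enum):
    """Mutually exclusive classes partitioning every protocol day."""

    VALID = "VALID"
    PC_NONWEAR = "PC_NONWEAR"
    NPC_NONWEAR = "NPC_NONWEAR"
    CHANGEOVER = "CHANGEOVER"
    POST_WITHDRAWAL = "POST_WITHDRAWAL"


#: Study-logistics reasons a day can be lost outside participant control.
NPC_REASONS = ("damaged", "misconfigured", "non_fitting", "lost", "delayed", "systemic")

ARCHETYPES = ("optimal", "moderate", "low")
SCHEDULE_TYPES = ("biweekly", "monthly", "both")
SMOKING_LEVELS = ("never", "active", "previous")


class ConfigurationError(ValueError):
    """Invalid cohort or pipeline configuration."""


class DomainError(ValueError):
    """Input outside its documented domain (e.g. wear hours not in [0, 24])."""


class AccountingError(ValueError):
    """Inconsistent day accounting (incomplete records, valid > expected...)."""


class MalformedStreamError(ValueError):
    """Epoch stream with gaps, duplicates or non-uniform spacing."""


class DegenerateGroupError(ValueError):
    """A grouped comparison where some group is empty."""


class CollinearityError(ValueError):
    """Singular regression design; carries the offending term names."""

    def __init__(self, terms):
        self.terms = tuple(terms)
        super().__init__(f"collinear design columns: {', '.join(self.terms)}")


@dataclass(frozen=True)
class ParticipantProfile:
    """Baseline covariates for one participant.

    ``kccq_clinical`` is the Kansas City Cardiomyopathy Questionnaire
    clinical summary score (0-100, higher = better health status).
    """

    participant_id: str
    age_years: float
    sex: str  # {"female", "male"}
    device_type: str  # {"ICD", "CRT-D"}
    known_af: bool
    hf_hospitalization: bool
    cardiovascular_comorbidity: bool
    smoking: str  # {"never", "active", "previous"}
    kccq_clinical: float
    centre: str  # {"A", "B"}
    schedule_type: str  # {"biweekly", "monthly", "both"}
    withdrawal_day: Optional[int] = None

    def __post_init__(self):
        if self.age_years <= 0:
            raise DomainError(f"age_years must be positive, got {self.age_years}")
        if not 0.0 <= self.kccq_clinical <= 100.0:
            raise DomainError(f"kccq_clinical outside [0, 100]: {self.kccq_clinical}")
        if self.sex not in ("female", "male"):
            raise DomainError(f"unknown sex {self.sex!r}")
        if self.device_type not in ("ICD", "CRT-D"):
            raise DomainError(f"unknown device_type {self.device_type!r}")
        if self.smoking not in SMOKING_LEVELS:
            raise DomainError(f"unknown smoking level {self.smoking!r}")
        if self.schedule_type not in SCHEDULE_TYPES:
            raise DomainError(f"unknown schedule_type {self.schedule_type!r}")
        if self.withdrawal_day is not None and self.withdrawal_day < 1:
            raise DomainError("withdrawal_day must be a study-day index >= 1")


@dataclass(frozen=True)
class DeploymentSchedule:
    """Device logistics timeline for one participant.

    ``changeover_days`` are study days on which the participant swapped
    the old device for a newly delivered one (systemic loss inherent to
    the protocol).  ``npc_nonwear_days`` maps study days lost outside
    participant control to their reason (damaged, lost, delayed, ...).
    """

    participant_id: str
    enrolment_date: date
    changeover_days: frozenset = frozenset()
    npc_nonwear_days: Mapping[int, str] = field(default_factory=dict)
    withdrawal_day: Optional[int] = None

    def __post_init__(self):
        overlap = set(self.changeover_days) & set(self.npc_nonwear_days)
        if overlap:
            raise ConfigurationError(
                f"changeover and NPC non-wear days overlap: {sorted(overlap)}"
            )
        bad = [r for r in self.npc_nonwear_days.values() if r not in NPC_REASONS]
        if bad:
            raise ConfigurationError(f"unknown NPC non-wear reasons: {sorted(set(bad))}")

    def validate_range(self, protocol_days: int) -> None:
        for d in list(self.changeover_days) + list(self.npc_nonwear_days):
            if not 1 <= d <= protocol_days:
                raise ConfigurationError(
                    f"schedule day {d} outside [1, {protocol_days}] "
                    f"for {self.participant_id}"
                )
        if self.withdrawal_day is not None and not (
            1 <= self.withdrawal_day <= protocol_days
        ):
            raise ConfigurationError(
                f"withdrawal_day {self.withdrawal_day} outside [1, {protocol_days}]"
            )


@dataclass(frozen=True)
class WearSegment:
    """A maximal run of epochs sharing one worn/off-body state."""

    start: datetime
    end: datetime
    worn: bool

    def __post_init__(self):
        if self.end <= self.start:
            raise DomainError("segment end must be after start")

    @property
    def hours(self) -> float:
        return (self.end - self.start).total_seconds() / 3600.0


@dataclass(frozen=True)
class AdherenceSummary:
    """Per-participant adherence scores and group labels.

    ``long_term_adherence`` and the period adherences are NaN when the
    corresponding expected-day denominator is zero (flagged-undefined);
    such participants are excluded from cohort medians and classified
    ``low`` for trajectory tables.
    """

    participant_id: str
    valid_days: int
    expected_days: int
    long_term_adherence: float  # NaN when expected_days == 0
    mean_daily_adherence: float  # NaN when no qualifying day
    lt_group: str
    daily_group: str
    period_lt_adherence: Tuple[float, float, float]
    period_lt_groups: Tuple[str, str, str]  # group label or "dropped_out"
    data_return: float


@dataclass(frozen=True)
class EffectEstimate:
    """One exponentiated regression coefficient (a relative effect)."""

    term: str
    relative_effect: float
    ci95: Tuple[float, float]
    p_value: float

    def __post_init__(self):
        lo, hi = self.ci95
        if not lo <= self.relative_effect <= hi:
            raise DomainError(
                f"CI ({lo}, {hi}) does not bracket estimate {self.relative_effect}"
            )


@dataclass(frozen=True)
class GroupComparison:
    """Result of a between-group hypothesis test."""

    variable: str
    test_name: str
    statistic: float
    p_value: float
    n_groups: int
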