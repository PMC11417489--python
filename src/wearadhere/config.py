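"""Validated configuration models (pydantic) and YAML loading.

``CohortConfig`` holds the synthetic-cohort generating model,
``DetectionConfig`` the non-wear detection heuristic, and
``PipelineConfig`` the end-to-end run.  A single YAML file with nested
sections maps onto ``PipelineConfig``; see ``examples/pipeline.yaml``.
"""

from __future__ import annotations

import datetime as _dt
from typing import Optional, Tuple

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .types import ConfigurationError


class CohortConfig(BaseModel):
    """Generating model for a synthetic wearable-adherence cohort.

    Adherence propensity is generated on the log scale: each participant
    draws an archetype (optimal / moderate / low wear behaviour) and the
    log of their valid-day probability is

        log(baseline[archetype])
        + log(age_effect_per_decade) * (age - age_reference) / 10
        + log(monthly_schedule_effect) * 1{monthly schedule}
        + log(both_schedule_effect) * 1{mixed schedule}
        - frailty,   frailty = |Normal(0, frailty_sd)|

    capped at ``log(adherence_cap)``.  The one-sided frailty models
    lapses below a personal ceiling; the multiplicative covariate
    effects match the relative-effect scale of a linear regression on
    log-transformed long-term adherence, so an OLS fit on generated
    cohorts recovers the configured effects.
    """

    n_participants: int = Field(gt=0)
    protocol_days: int = Field(default=182, ge=1)
    archetype_mix: Tuple[float, float, float] = (0.28, 0.429, 0.291)
    # Truncated-normal age model (years); location/scale from the target
    # population (median 64, IQR 57-72 in ICD carriers).
    age_loc: float = 64.0
    age_scale: float = 11.0
    age_min: float = 35.0
    age_max: float = 88.0
    age_reference: float = 64.0
    age_effect_per_decade: float = Field(default=1.14, gt=0)
    schedule_mix: Tuple[float, float, float] = (0.35, 0.35, 0.30)  # biweekly, monthly, both
    monthly_schedule_effect: float = Field(default=1.24, gt=0)
    both_schedule_effect: float = Field(default=1.09, gt=0)
    withdrawal_hazard_low: float = Field(default=0.002, ge=0, le=1)
    npc_nonwear_rate: float = Field(default=0.8, ge=0)  # expected NPC days per deployment
    npc_span_mean_days: float = Field(default=3.0, gt=0)
    changeover_interval_days: dict = Field(
        default_factory=lambda: {"biweekly": 14, "monthly": 28}
    )
    #: study day up to which the mixed ("both") schedule runs biweekly
    both_switch_day: int = 60
    epoch_seconds: int = Field(default=60, gt=0)
    # Archetype baselines: valid-day probability at reference age on the
    # biweekly schedule, before frailty.  See docs/methods.md for the
    # ceiling-versus-estimability trade behind these values.
    baseline_optimal: float = Field(default=0.84, gt=0, le=1)
    baseline_moderate: float = Field(default=0.70, gt=0, le=1)
    baseline_low: float = Field(default=0.38, gt=0, le=1)
    frailty_sd: float = Field(default=0.22, ge=0)
    adherence_cap: float = Field(default=0.995, gt=0, le=1)
    #: lag-1 autocorrelation of the day-level valid/invalid process
    day_autocorrelation: float = Field(default=0.0, ge=0, lt=1)
    #: amplitude of a log-scale sinusoidal seasonal effect on wear (0 = none)
    seasonal_amplitude: float = Field(default=0.0, ge=0)
    seasonal_peak_month: int = Field(default=6, ge=1, le=12)
    # Covariate frequencies (cohort composition, not effects).
    female_fraction: float = 0.19
    crtd_fraction: float = 0.19
    af_fraction: float = 0.35
    hf_hospitalization_fraction: float = 0.074
    comorbidity_fraction: float = 0.70
    smoking_mix: Tuple[float, float, float] = (0.41, 0.14, 0.45)  # never, active, previous
    kccq_loc: float = 75.0
    kccq_scale: float = 18.0
    centre_a_fraction: float = 0.5
    enrolment_start: _dt.date = _dt.date(2021, 5, 1)
    enrolment_end: _dt.date = _dt.date(2022, 9, 30)
    seed: int = 0

    @field_validator("archetype_mix", "schedule_mix", "smoking_mix")
    @classmethod
    def _mix_sums_to_one(cls, v):
        if any(w < 0 for w in v):
            raise ValueError(f"mixture weights must be non-negative: {v}")
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {sum(v)}")
        return v

    @model_validator(mode="after")
    def _check(self):
        if 86400 % self.epoch_seconds != 0:
            raise ValueError(f"epoch_seconds must divide 86400, got {self.epoch_seconds}")
        for name in ("biweekly", "monthly"):
            iv = self.changeover_interval_days.get(name)
            if not isinstance(iv, int) or iv < 1:
                raise ValueError(f"changeover_interval_days[{name!r}] must be a positive int")
        if self.enrolment_end < self.enrolment_start:
            raise ValueError("enrolment_end before enrolment_start")
        return self

    model_config = {"frozen": True}


class DetectionConfig(BaseModel):
    """Sliding-window non-wear heuristic parameters.

    An epoch is an off-body *candidate* when its movement dispersion is
    below ``movement_threshold`` (gravity units) and its near-body
    temperature below ``temperature_threshold_c``.  Candidate runs
    shorter than ``window_minutes`` stay worn (ties resolve toward
    worn), so detected non-wear is resolved at the window scale.
    """

    window_minutes: float = Field(default=30.0, gt=0)
    movement_threshold: float = Field(default=0.013, gt=0)
    temperature_threshold_c: float = 25.0

    model_config = {"frozen": True}


class RegressionConfig(BaseModel):
    """Options for the log-linear adherence regression."""

    zero_handling: str = Field(default="exclude", pattern="^(exclude|offset_epsilon)$")
    epsilon: float = Field(default=0.005, gt=0)

    model_config = {"frozen": True}


class PipelineConfig(BaseModel):
    """End-to-end run: simulate -> detect -> account -> score -> associate."""

    cohort: CohortConfig
    detection: DetectionConfig = DetectionConfig()
    regression: RegressionConfig = RegressionConfig()
    valid_threshold_hours: float = Field(default=22.0, ge=0, le=24)
    period_edges: Tuple[int, int] = (60, 120)
    #: number of participant-days to emit as epoch-level CSV (0 = none)
    emit_epoch_days: int = Field(default=0, ge=0)
    make_figures: bool = False
    count_post_withdrawal_in_expected: bool = True
    daily_denominator: str = Field(
        default="positive_wear", pattern="^(positive_wear|expected)$"
    )

    model_config = {"frozen": True}


def load_config(path) -> PipelineConfig:
    """Read a YAML pipeline config; raise ConfigurationError on problems."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    try:
        return PipelineConfig(**raw)
    except Exception as exc:  # pydantic ValidationError -> domain error
        raise ConfigurationError(f"{path}: {exc}") from exc
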