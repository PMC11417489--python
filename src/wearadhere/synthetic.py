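"""Synthetic cohort generator for long-term wearable-adherence studies.

Emulates a 182-day protocol in which participants wear a wrist device
day and night, devices are swapped by courier on a biweekly or monthly
cadence, days are lost to logistics (damaged / lost / delayed devices),
and low-engagement participants may withdraw early.  Adherence
propensity is generated on the log scale so that the multiplicative
covariate effects used as generating truth are directly comparable to
the relative effects estimated by a linear regression on log-transformed
long-term adherence (see :mod:`wearadhere.stats`).

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from datetime import date, timedelta
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import CohortConfig
from .types import (
    ARCHETYPES,
    ConfigurationError,
    DeploymentSchedule,
    DomainError,
    ParticipantProfile,
    SCHEDULE_TYPES,
    SMOKING_LEVELS,
)

__all__ = [
    "generate_cohort",
    "generate_epoch_stream",
    "inject_logistics_events",
    "build_schedule",
    "expected_log_adherence",
    "write_cohort",
]

# Epoch-level emission distributions (movement dispersion in g,
# near-body temperature in deg C).  Worn wrists move and are warm;
# off-body devices are stationary and at ambient temperature.
_WORN_MOVEMENT_SHAPE = 2.0
_WORN_MOVEMENT_SCALE = 0.05
_WORN_TEMP_MEAN = 32.0
_WORN_TEMP_SD = 1.5
_OFF_MOVEMENT_SD = 0.002
_OFF_TEMP_MEAN = 21.0
_OFF_TEMP_SD = 1.0


def _archetype_baseline(config: CohortConfig) -> dict:
    return {
        "optimal": config.baseline_optimal,
        "moderate": config.baseline_moderate,
        "low": config.baseline_low,
    }


def expected_log_adherence(
    archetype: str, age_years: float, schedule_type: str, config: CohortConfig
) -> float:
    """Systematic part of the log valid-day probability (before frailty/cap)."""
    eta = math.log(_archetype_baseline(config)[archetype])
    eta += math.log(config.age_effect_per_decade) * (age_years - config.age_reference) / 10.0
    if schedule_type == "monthly":
        eta += math.log(config.monthly_schedule_effect)
    elif schedule_type == "both":
        eta += math.log(config.both_schedule_effect)
    return eta


def _changeover_days(schedule_type: str, config: CohortConfig) -> frozenset:
    """Study days on which the participant swaps devices.

    The final return at protocol end is not a swap, so cadence
    boundaries equal to ``protocol_days`` are excluded: a biweekly
    cadence over 182 days yields 12 changeover days.
    """
    n = config.protocol_days
    biweekly = config.changeover_interval_days["biweekly"]
    monthly = config.changeover_interval_days["monthly"]
    days: List[int] = []
    if schedule_type == "biweekly":
        days = list(range(biweekly, n, biweekly))
    elif schedule_type == "monthly":
        days = list(range(monthly, n, monthly))
    elif schedule_type == "both":
        d = biweekly
        while d <= config.both_switch_day and d < n:
            days.append(d)
            d += biweekly
        d = days[-1] + monthly if days else monthly
        while d < n:
            days.append(d)
            d += monthly
    else:
        raise ConfigurationError(f"unknown schedule_type {schedule_type!r}")
    return frozenset(days)


def build_schedule(
    participant_id: str,
    enrolment_date: date,
    schedule_type: str,
    config: CohortConfig,
    withdrawal_day: Optional[int] = None,
) -> DeploymentSchedule:
    """Deployment timeline with changeover days but no logistics incidents."""
    return DeploymentSchedule(
        participant_id=participant_id,
        enrolment_date=enrolment_date,
        changeover_days=_changeover_days(schedule_type, config),
        npc_nonwear_days={},
        withdrawal_day=withdrawal_day,
    )


def inject_logistics_events(
    schedule: DeploymentSchedule, config: CohortConfig, rng: np.random.Generator
) -> DeploymentSchedule:
    """Insert non-participant-controlled non-wear spans into a schedule.

    The expected number of lost days is ``npc_nonwear_rate`` per
    deployment (deployments = changeovers + 1); days are grouped into
    contiguous spans (a delayed or damaged device costs several days in
    a row) and spans never overlap changeover days.  Rate 0 is a no-op.
    """
    n_deployments = len(schedule.changeover_days) + 1
    total = int(rng.poisson(config.npc_nonwear_rate * n_deployments))
    if total == 0:
        return schedule
    npc: dict = {}
    blocked = set(schedule.changeover_days)
    remaining = total
    attempts = 0
    while remaining > 0 and attempts < 200:
        attempts += 1
        span = min(1 + int(rng.geometric(1.0 / config.npc_span_mean_days)) - 1, remaining)
        span = max(span, 1)
        start = int(rng.integers(1, config.protocol_days + 1))
        reason = str(rng.choice(["damaged", "misconfigured", "non_fitting", "lost", "delayed"]))
        for d in range(start, min(start + span, config.protocol_days + 1)):
            if d in blocked or d in npc:
                continue  # never overlap changeover days
            npc[d] = reason
            remaining -= 1
            if remaining == 0:
                break
    return DeploymentSchedule(
        participant_id=schedule.participant_id,
        enrolment_date=schedule.enrolment_date,
        changeover_days=schedule.changeover_days,
        npc_nonwear_days=npc,
        withdrawal_day=schedule.withdrawal_day,
    )


def _truncnorm(rng, loc, scale, lo, hi, size=None):
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return sps.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def _seasonal_factor(month: np.ndarray, config: CohortConfig) -> np.ndarray:
    if config.seasonal_amplitude == 0.0:
        return np.ones_like(month, dtype=float)
    phase = 2.0 * np.pi * (month - config.seasonal_peak_month) / 12.0
    return np.exp(config.seasonal_amplitude * np.cos(phase))


def _daily_wear_for_participant(
    q: float,
    schedule: DeploymentSchedule,
    dates: np.ndarray,
    config: CohortConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw wear hours for study days 1..protocol_days.

    Valid days lose under 2 h to brief removals; invalid (participant-
    controlled non-wear) days concentrate just under the 22 h line with
    a tail of mostly-off days; changeover days lose a swap gap; NPC and
    post-withdrawal days are zero.
    """
    n = config.protocol_days
    months = pd.DatetimeIndex(dates).month.to_numpy()
    q_day = np.clip(q * _seasonal_factor(months, config), 0.0, config.adherence_cap)

    # valid/invalid indicator, optionally with AR(1) Gaussian-copula
    # persistence so lapses cluster on consecutive days
    rho = config.day_autocorrelation
    z = rng.standard_normal(n)
    if rho > 0.0:
        for i in range(1, n):
            z[i] = rho * z[i - 1] + math.sqrt(1.0 - rho * rho) * z[i]
    u = sps.norm.cdf(z)
    valid = u < q_day

    wear = np.where(
        valid,
        24.0 - 2.0 * rng.beta(1.5, 4.0, size=n),  # (22, 24]
        22.0 * rng.beta(3.0, 1.0, size=n),  # [0, 22), mass near 22
    )
    # changeover: device swap costs a gap of a few hours
    co = np.array(sorted(schedule.changeover_days), dtype=int)
    if co.size:
        gap = rng.uniform(2.0, 8.0, size=co.size)
        wear[co - 1] = np.clip(24.0 - 2.0 * rng.beta(1.5, 4.0, size=co.size) - gap, 0.0, 24.0)
    for d in schedule.npc_nonwear_days:
        wear[d - 1] = 0.0
    if schedule.withdrawal_day is not None:
        wear[schedule.withdrawal_day - 1 :] = 0.0
    return np.clip(wear, 0.0, 24.0)


def generate_cohort(
    config: CohortConfig, seed: Optional[int] = None
) -> Tuple[List[ParticipantProfile], List[DeploymentSchedule], pd.DataFrame]:
    """Generate profiles, deployment schedules, and a day-level wear table.

    Returns ``(profiles, schedules, day_wear)`` where ``day_wear`` has
    one row per participant per protocol day with columns
    ``participant_id, study_day, date, wear_hours``.  Deterministic for
    a fixed seed (``config.seed`` unless overridden).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_participants

    archetypes = rng.choice(ARCHETYPES, size=n, p=config.archetype_mix)
    schedules_t = rng.choice(SCHEDULE_TYPES, size=n, p=config.schedule_mix)
    ages = _truncnorm(rng, config.age_loc, config.age_scale, config.age_min, config.age_max, n)
    female = rng.random(n) < config.female_fraction
    crtd = rng.random(n) < config.crtd_fraction
    af = rng.random(n) < config.af_fraction
    hf = rng.random(n) < config.hf_hospitalization_fraction
    comorbid = rng.random(n) < config.comorbidity_fraction
    smoking = rng.choice(SMOKING_LEVELS, size=n, p=config.smoking_mix)
    kccq = _truncnorm(rng, config.kccq_loc, config.kccq_scale, 0.0, 100.0, n)
    centre = np.where(rng.random(n) < config.centre_a_fraction, "A", "B")
    enrol_span = (config.enrolment_end - config.enrolment_start).days
    enrol_offsets = rng.integers(0, enrol_span + 1, size=n)

    profiles: List[ParticipantProfile] = []
    schedules: List[DeploymentSchedule] = []
    frames = []
    width = len(str(n))
    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        enrolment = config.enrolment_start + timedelta(days=int(enrol_offsets[i]))

        withdrawal_day: Optional[int] = None
        if archetypes[i] == "low" and config.withdrawal_hazard_low > 0.0:
            day = int(rng.geometric(config.withdrawal_hazard_low))
            if day <= config.protocol_days:
                withdrawal_day = day

        profile = ParticipantProfile(
            participant_id=pid,
            age_years=float(ages[i]),
            sex="female" if female[i] else "male",
            device_type="CRT-D" if crtd[i] else "ICD",
            known_af=bool(af[i]),
            hf_hospitalization=bool(hf[i]),
            cardiovascular_comorbidity=bool(comorbid[i]),
            smoking=str(smoking[i]),
            kccq_clinical=float(kccq[i]),
            centre=str(centre[i]),
            schedule_type=str(schedules_t[i]),
            withdrawal_day=withdrawal_day,
        )
        schedule = build_schedule(pid, enrolment, profile.schedule_type, config, withdrawal_day)
        schedule = inject_logistics_events(schedule, config, rng)

        eta = expected_log_adherence(str(archetypes[i]), profile.age_years,
                                     profile.schedule_type, config)
        eta -= abs(rng.normal(0.0, config.frailty_sd)) if config.frailty_sd > 0 else 0.0
        q = min(math.exp(eta), config.adherence_cap)

        dates = pd.date_range(enrolment, periods=config.protocol_days, freq="D")
        wear = _daily_wear_for_participant(q, schedule, dates.to_numpy(), config, rng)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "study_day": np.arange(1, config.protocol_days + 1),
                    "date": dates.date,
                    "wear_hours": wear,
                    "archetype": archetypes[i],
                }
            )
        )
        profiles.append(profile)
        schedules.append(schedule)

    day_wear = pd.concat(frames, ignore_index=True)
    return profiles, schedules, day_wear


def generate_epoch_stream(
    day_wear_hours: float,
    config: CohortConfig,
    rng: Optional[np.random.Generator] = None,
    day: date = date(2022, 1, 1),
) -> pd.DataFrame:
    """Epoch-level movement/temperature records for one civil day.

    The worn fraction of epochs equals ``day_wear_hours / 24`` exactly
    (to epoch resolution); non-wear is placed as a single contiguous
    bout at a random position, matching real removal behaviour and
    making window-based detection meaningful.  Columns: ``timestamp``,
    ``movement_summary`` (dispersion of acceleration magnitude, g),
    ``temperature_c``, ``worn_truth``.
    """
    if not 0.0 <= day_wear_hours <= 24.0:
        raise DomainError(f"day_wear_hours outside [0, 24]: {day_wear_hours}")
    rng = np.random.default_rng(0) if rng is None else rng
    n = 86400 // config.epoch_seconds
    n_worn = int(round(day_wear_hours / 24.0 * n))
    worn = np.ones(n, dtype=bool)
    n_off = n - n_worn
    if n_off > 0:
        start = int(rng.integers(0, n - n_off + 1))
        worn[start : start + n_off] = False

    movement = np.empty(n)
    temperature = np.empty(n)
    k = int(worn.sum())
    movement[worn] = rng.gamma(_WORN_MOVEMENT_SHAPE, _WORN_MOVEMENT_SCALE, size=k)
    temperature[worn] = rng.normal(_WORN_TEMP_MEAN, _WORN_TEMP_SD, size=k)
    movement[~worn] = np.abs(rng.normal(0.0, _OFF_MOVEMENT_SD, size=n - k))
    temperature[~worn] = rng.normal(_OFF_TEMP_MEAN, _OFF_TEMP_SD, size=n - k)

    timestamps = pd.date_range(
        pd.Timestamp(day), periods=n, freq=pd.Timedelta(seconds=config.epoch_seconds)
    )
    return pd.DataFrame(
        {
            "timestamp": timestamps,
            "movement_summary": movement,
            "temperature_c": temperature,
            "worn_truth": worn,
        }
    )


def _schedule_to_row(s: DeploymentSchedule) -> dict:
    return {
        "participant_id": s.participant_id,
        "enrolment_date": s.enrolment_date.isoformat(),
        "changeover_days": ";".join(str(d) for d in sorted(s.changeover_days)),
        "npc_nonwear_days": ";".join(
            f"{d}:{r}" for d, r in sorted(s.npc_nonwear_days.items())
        ),
        "withdrawal_day": "" if s.withdrawal_day is None else s.withdrawal_day,
    }


def schedules_to_frame(schedules: Sequence[DeploymentSchedule]) -> pd.DataFrame:
    return pd.DataFrame([_schedule_to_row(s) for s in schedules])


def schedules_from_frame(df: pd.DataFrame) -> List[DeploymentSchedule]:
    """Inverse of :func:`schedules_to_frame` (reads schedules.csv)."""
    out = []
    for row in df.itertuples(index=False):
        co = frozenset(
            int(x) for x in str(row.changeover_days).split(";") if x not in ("", "nan")
        )
        npc = {}
        for item in str(row.npc_nonwear_days).split(";"):
            if item and item != "nan":
                d, reason = item.split(":")
                npc[int(d)] = reason
        wd = row.withdrawal_day
        wd = None if (pd.isna(wd) or wd == "") else int(float(wd))
        out.append(
            DeploymentSchedule(
                participant_id=str(row.participant_id),
                enrolment_date=date.fromisoformat(str(row.enrolment_date)),
                changeover_days=co,
                npc_nonwear_days=npc,
                withdrawal_day=wd,
            )
        )
    return out


def profiles_to_frame(profiles: Sequence[ParticipantProfile]) -> pd.DataFrame:
    df = pd.DataFrame([p.__dict__ for p in profiles])
    return df


def write_cohort(profiles, schedules, day_wear: pd.DataFrame, outdir) -> dict:
    """Write participants.csv, schedules.csv, day_wear.csv; return paths."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "participants": outdir / "participants.csv",
        "schedules": outdir / "schedules.csv",
        "day_wear": outdir / "day_wear.csv",
    }
    profiles_to_frame(profiles).to_csv(paths["participants"], index=False)
    schedules_to_frame(schedules).to_csv(paths["schedules"], index=False)
    day_wear.to_csv(paths["day_wear"], index=False)
    return {k: str(v) for k, v in paths.items()}
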