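"""End-to-end orchestration: simulate -> detect -> account -> score ->
associate -> report, with a run manifest for provenance and resume.

All intermediate artifacts are plain CSV with documented columns, so
any stage can be fed real exported wearable data in place of the
simulator.  Identical config + seed produces byte-identical outputs; a
stage is skipped on re-run when its outputs already match the
checksums recorded in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
from datetime import datetime, timezone
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .adherence import cohort_summary, summarize_cohort
from .config import PipelineConfig, load_config
from .day_accounting import build_day_records
from .stats import (
    RegressionSpec,
    baseline_comparisons,
    fit_log_linear,
    seasonality_profile,
    sensitivity_split,
)
from .synthetic import (
    generate_cohort,
    generate_epoch_stream,
    schedules_from_frame,
    write_cohort,
)
from .types import AccountingError, ConfigurationError
from .wear_detection import classify_epoch_wear, daily_wear_hours

log = logging.getLogger("wearadhere")

STAGES = ("simulate", "detect", "account", "score", "associate", "report")

#: required columns per intermediate CSV (schema validation on read)
SCHEMAS = {
    "day_wear.csv": ["participant_id", "study_day", "date", "wear_hours"],
    "schedules.csv": [
        "participant_id",
        "enrolment_date",
        "changeover_days",
        "npc_nonwear_days",
        "withdrawal_day",
    ],
    "participants.csv": ["participant_id", "age_years", "sex", "schedule_type"],
    "day_records.csv": ["participant_id", "study_day", "wear_hours", "day_class"],
    "adherence_summary.csv": [
        "participant_id",
        "valid_days",
        "expected_days",
        "long_term_adherence",
    ],
}


def _sha256(path: pathlib.Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: PipelineConfig, seed: int) -> str:
    payload = json.dumps(
        {"config": config.model_dump(mode="json"), "seed": seed}, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def _read_csv(path: pathlib.Path, schema_key: str) -> pd.DataFrame:
    if not path.exists():
        raise AccountingError(f"missing stage input: {path}")
    df = pd.read_csv(path)
    missing = [c for c in SCHEMAS[schema_key] if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing columns {missing}")
    return df


class RunManifest:
    """Provenance of one pipeline run (JSON-serializable)."""

    def __init__(self, config_hash: str, seed: int, path: pathlib.Path):
        self.config_hash = config_hash
        self.seed = seed
        self.path = path
        self.version = __version__
        self.stages: Dict[str, dict] = {}

    @classmethod
    def load(cls, path: pathlib.Path) -> Optional["RunManifest"]:
        if not path.exists():
            return None
        raw = json.loads(path.read_text())
        m = cls(raw["config_hash"], raw["seed"], path)
        m.version = raw.get("version", "?")
        m.stages = raw.get("stages", {})
        return m

    def record(self, stage: str, outputs: Sequence[pathlib.Path]) -> None:
        outdir = self.path.parent
        self.stages[stage] = {
            "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
            "completed_at": datetime.now(timezone.utc).isoformat(),
        }
        self.save()

    def save(self) -> None:
        self.path.write_text(
            json.dumps(
                {
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "version": self.version,
                    "stages": self.stages,
                },
                indent=2,
            )
        )

    def outputs_fresh(self, stage: str, outdir: pathlib.Path) -> bool:
        info = self.stages.get(stage)
        if not info:
            return False
        for name, digest in info["outputs"].items():
            p = outdir / name
            if not p.exists() or _sha256(p) != digest:
                return False
        return True


def run_pipeline(
    config: PipelineConfig,
    outdir,
    seed: Optional[int] = None,
    stages: Optional[Sequence[str]] = None,
) -> RunManifest:
    """Run (or resume) the pipeline; returns the run manifest.

    A stage re-executes only when its recorded outputs are missing or
    stale, or when config/seed changed since the previous run.
    """
    if isinstance(config, (str, pathlib.Path)):
        config = load_config(config)
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.cohort.seed if seed is None else int(seed)
    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages: {sorted(unknown)}")

    chash = _config_hash(config, seed)
    manifest = RunManifest.load(outdir / "manifest.json")
    if manifest is None or manifest.config_hash != chash:
        manifest = RunManifest(chash, seed, outdir / "manifest.json")

    for stage in STAGES:
        if stage not in stages:
            continue
        if manifest.outputs_fresh(stage, outdir):
            log.info("stage %s: outputs fresh, skipping", stage)
            continue
        log.info("stage %s: running", stage)
        outputs = _RUNNERS[stage](config, outdir, seed)
        manifest.record(stage, outputs)
    return manifest


# --------------------------------------------------------------------------
# stage runners (each returns the list of files it wrote)

def _stage_simulate(config: PipelineConfig, outdir: pathlib.Path, seed: int):
    profiles, schedules, day_wear = generate_cohort(config.cohort, seed=seed)
    paths = write_cohort(profiles, schedules, day_wear, outdir)
    written = [pathlib.Path(p) for p in paths.values()]
    if config.emit_epoch_days > 0:
        rng = np.random.default_rng(seed + 1)
        epoch_dir = outdir / "epochs"
        epoch_dir.mkdir(exist_ok=True)
        sample = day_wear.sample(
            n=min(config.emit_epoch_days, len(day_wear)), random_state=int(seed % 2**31)
        )
        for row in sample.itertuples(index=False):
            stream = generate_epoch_stream(
                float(row.wear_hours), config.cohort, rng, day=pd.Timestamp(row.date).date()
            )
            p = epoch_dir / f"{row.participant_id}_day{row.study_day:03d}.csv"
            stream.drop(columns=["worn_truth"]).to_csv(p, index=False)
            written.append(p)
    return written


def _stage_detect(config: PipelineConfig, outdir: pathlib.Path, seed: int):
    """Run non-wear detection over any emitted epoch files.

    Produces detected_day_wear.csv comparing the detector's daily wear
    hours with the simulator's day-level values for the sampled days.
    When no epoch files exist the stage records an empty comparison
    (the day-level path is authoritative).
    """
    epoch_dir = outdir / "epochs"
    rows = []
    if epoch_dir.exists():
        for p in sorted(epoch_dir.glob("*.csv")):
            stream = pd.read_csv(p)
            segments = classify_epoch_wear(stream, config.detection)
            daily = daily_wear_hours(segments)
            pid, day_part = p.stem.rsplit("_day", 1)
            full = daily[~daily["partial_day"]]
            detected = float(full["wear_hours"].iloc[0]) if len(full) else float("nan")
            rows.append(
                {
                    "participant_id": pid,
                    "study_day": int(day_part),
                    "detected_wear_hours": detected,
                }
            )
    out = outdir / "detected_day_wear.csv"
    pd.DataFrame(rows, columns=["participant_id", "study_day", "detected_wear_hours"]).to_csv(
        out, index=False
    )
    return [out]


def _stage_account(config: PipelineConfig, outdir: pathlib.Path, seed: int):
    day_wear = _read_csv(outdir / "day_wear.csv", "day_wear.csv")
    schedules = schedules_from_frame(_read_csv(outdir / "schedules.csv", "schedules.csv"))
    records = build_day_records(
        day_wear,
        schedules,
        valid_threshold_hours=config.valid_threshold_hours,
        protocol_days=config.cohort.protocol_days,
    )
    out = outdir / "day_records.csv"
    records.to_csv(out, index=False)
    return [out]


def _stage_score(config: PipelineConfig, outdir: pathlib.Path, seed: int):
    records = _read_csv(outdir / "day_records.csv", "day_records.csv")
    summaries = summarize_cohort(
        records,
        protocol_days=config.cohort.protocol_days,
        period_edges=config.period_edges,
        count_post_withdrawal=config.count_post_withdrawal_in_expected,
        daily_denominator=config.daily_denominator,
    )
    out = outdir / "adherence_summary.csv"
    summaries.to_csv(out, index=False)
    return [out]


def _stage_associate(config: PipelineConfig, outdir: pathlib.Path, seed: int):
    summaries = _read_csv(outdir / "adherence_summary.csv", "adherence_summary.csv")
    profiles = _read_csv(outdir / "participants.csv", "participants.csv")
    records = _read_csv(outdir / "day_records.csv", "day_records.csv")

    table1 = baseline_comparisons(summaries, profiles)
    spec = RegressionSpec(
        zero_handling=config.regression.zero_handling, epsilon=config.regression.epsilon
    )
    effects = fit_log_linear(summaries, profiles, spec)
    table2 = pd.DataFrame(
        {
            "term": [e.term for e in effects],
            "relative_effect": [e.relative_effect for e in effects],
            "ci_low": [e.ci95[0] for e in effects],
            "ci_high": [e.ci95[1] for e in effects],
            "p_value": [e.p_value for e in effects],
        }
    )
    seasonality = seasonality_profile(records).reset_index()
    seasonality.columns = ["month", "mean_daily_adherence"]
    sens = sensitivity_split(summaries, profiles)

    paths = {
        "table1.csv": table1,
        "table2.csv": table2,
        "seasonality.csv": seasonality,
        "sensitivity.csv": sens,
    }
    written = []
    for name, df in paths.items():
        p = outdir / name
        df.to_csv(p, index=False)
        written.append(p)
    return written


def _stage_report(config: PipelineConfig, outdir: pathlib.Path, seed: int):
    summaries = _read_csv(outdir / "adherence_summary.csv", "adherence_summary.csv")
    profiles = _read_csv(outdir / "participants.csv", "participants.csv")
    report = cohort_summary(summaries, profiles, config.cohort.protocol_days)

    written = []
    for key in ("lt_group_counts", "daily_group_counts", "trajectories", "schedule_by_group"):
        p = outdir / f"{key}.csv"
        report[key].to_csv(p, index=False)
        written.append(p)
    scalars = {
        k: report[k]
        for k in (
            "n_participants",
            "theoretical_max_days",
            "total_valid_days",
            "long_term_adherence_median_iqr",
            "daily_adherence_median_iqr",
            "data_return_median_iqr",
            "valid_days_median_iqr",
        )
    }
    p = outdir / "cohort_summary.json"
    p.write_text(json.dumps(scalars, indent=2, default=list))
    written.append(p)
    if config.make_figures:
        from .report import make_figures

        written += make_figures(summaries, profiles, outdir)
    return written


_RUNNERS = {
    "simulate": _stage_simulate,
    "detect": _stage_detect,
    "account": _stage_account,
    "score": _stage_score,
    "associate": _stage_associate,
    "report": _stage_report,
}
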