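"""Epoch-level non-wear detection and daily wear-hour summaries.

The detector is a documented stand-in for the device vendor's
processing chain: a wrist device that is stationary (movement
dispersion below a threshold) *and* cold (near-body temperature below a
body-proximity threshold) for at least a full detection window is
off-body.  Candidate runs shorter than the window stay worn, so ties at
window edges resolve toward "worn", biasing against over-counting
non-wear.
"""

from __future__ import annotations

from datetime import timedelta
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .config import DetectionConfig
from .types import MalformedStreamError, WearSegment

__all__ = ["classify_epoch_wear", "daily_wear_hours"]


def _validate_stream(epochs: pd.DataFrame) -> int:
    """Check strict increase and uniform spacing; return epoch seconds."""
    required = {"timestamp", "movement_summary", "temperature_c"}
    missing = required - set(epochs.columns)
    if missing:
        raise MalformedStreamError(f"epoch stream missing columns: {sorted(missing)}")
    if len(epochs) < 2:
        raise MalformedStreamError("epoch stream needs at least two epochs")
    ts = pd.to_datetime(epochs["timestamp"]).to_numpy()
    diffs = np.diff(ts).astype("timedelta64[s]").astype(np.int64)
    if (diffs <= 0).any():
        raise MalformedStreamError("timestamps must be strictly increasing")
    if np.unique(diffs).size != 1:
        raise MalformedStreamError(
            "non-uniform epoch spacing (resample before classification)"
        )
    return int(diffs[0])


def classify_epoch_wear(
    epochs: pd.DataFrame, params: Optional[DetectionConfig] = None
) -> List[WearSegment]:
    """Assign worn/off-body states and merge them into segments.

    Parameters
    ----------
    epochs
        Uniform, gapless stream with columns ``timestamp``,
        ``movement_summary`` (g) and ``temperature_c``.
    params
        Detection thresholds; defaults to :class:`DetectionConfig`.

    Returns
    -------
    list of WearSegment tiling the stream without gaps or overlaps.
    """
    params = params or DetectionConfig()
    epoch_seconds = _validate_stream(epochs)
    window_epochs = max(1, int(round(params.window_minutes * 60.0 / epoch_seconds)))

    movement = epochs["movement_summary"].to_numpy(dtype=float)
    temperature = epochs["temperature_c"].to_numpy(dtype=float)
    candidate = (movement < params.movement_threshold) & (
        temperature < params.temperature_threshold_c
    )

    # Off-body = candidate run of at least one full window; shorter runs
    # remain worn.
    worn = np.ones(len(epochs), dtype=bool)
    n = len(candidate)
    i = 0
    while i < n:
        if candidate[i]:
            j = i
            while j < n and candidate[j]:
                j += 1
            if j - i >= window_epochs:
                worn[i:j] = False
            i = j
        else:
            i += 1

    ts = pd.to_datetime(epochs["timestamp"]).reset_index(drop=True)
    step = timedelta(seconds=epoch_seconds)
    segments: List[WearSegment] = []
    start = 0
    for k in range(1, n + 1):
        if k == n or worn[k] != worn[start]:
            segments.append(
                WearSegment(
                    start=ts[start].to_pydatetime(),
                    end=ts[k - 1].to_pydatetime() + step,
                    worn=bool(worn[start]),
                )
            )
            start = k
    return segments


def daily_wear_hours(segments: Sequence[WearSegment]) -> pd.DataFrame:
    """Sum worn time within each civil day [midnight, next midnight).

    Returns a frame with columns ``date``, ``wear_hours`` (in [0, 24])
    and ``coverage_hours`` (worn + off-body time observed that day;
    ``partial_day`` flags days the stream does not fully cover).  Day
    boundaries are civil midnight in the stream's own clock.
    """
    if not segments:
        return pd.DataFrame(columns=["date", "wear_hours", "coverage_hours", "partial_day"])
    start = min(s.start for s in segments)
    end = max(s.end for s in segments)
    first = pd.Timestamp(start).normalize()
    days = pd.date_range(first, pd.Timestamp(end) - pd.Timedelta(microseconds=1), freq="D")

    rows = []
    for day in days:
        day_start, day_end = day, day + pd.Timedelta(days=1)
        worn_s = 0.0
        covered_s = 0.0
        for seg in segments:
            lo = max(pd.Timestamp(seg.start), day_start)
            hi = min(pd.Timestamp(seg.end), day_end)
            if hi > lo:
                dur = (hi - lo).total_seconds()
                covered_s += dur
                if seg.worn:
                    worn_s += dur
        rows.append(
            {
                "date": day.date(),
                "wear_hours": worn_s / 3600.0,
                "coverage_hours": covered_s / 3600.0,
                "partial_day": covered_s < 86400.0 - 1e-6,
            }
        )
    return pd.DataFrame(rows)
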