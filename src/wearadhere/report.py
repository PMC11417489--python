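"""Optional figures mirroring the standard adherence-report layout:
adherence versus days in study, per-day group means, and the
schedule-by-group distribution."""

from __future__ import annotations

import pathlib

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

GROUP_ORDER = ["optimal", "moderate", "low"]
GROUP_COLORS = {"optimal": "#2c7fb8", "moderate": "#7fcdbb", "low": "#edf8b1"}


def make_figures(summaries: pd.DataFrame, profiles: pd.DataFrame, outdir) -> list:
    outdir = pathlib.Path(outdir)
    written = []

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(
        summaries["expected_days"],
        100 * summaries["long_term_adherence"],
        s=12,
        alpha=0.6,
    )
    ax.set_xlabel("days in study with expected wear")
    ax.set_ylabel("long-term adherence (%)")
    p = outdir / "fig_adherence_vs_days.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(p)

    merged = summaries.merge(profiles, on="participant_id")
    counts = (
        merged.groupby(["schedule_type", "lt_group"]).size().unstack(fill_value=0)
    )
    counts = counts.reindex(columns=GROUP_ORDER, fill_value=0)
    fig, ax = plt.subplots(figsize=(6, 4))
    counts.plot.bar(
        stacked=True, ax=ax, color=[GROUP_COLORS[g] for g in counts.columns]
    )
    ax.set_ylabel("participants")
    ax.set_xlabel("changeover schedule")
    p = outdir / "fig_schedule_by_group.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(p)
    return written
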