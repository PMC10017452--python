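"""Figure analogues of the study's summary plots.

Every plot writes a CSV sidecar carrying exactly the plotted matrix or
table, so figure content is testable without image comparison.  Colour
scales are fixed per run for cross-group comparability.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .datamodel import ActivitySeries, LightSchedule
from .phases import assign_phases


def activity_day_matrix(
    act: ActivitySeries, schedule: LightSchedule
) -> pd.DataFrame:
    """Days × minutes-post-lights-on matrix of minute activity (no resampling)."""
    labels = assign_phases(act.timestamps(), schedule)
    df = labels.assign(value=act.values)
    mat = df.pivot_table(
        index="day", columns="minute_post_lights_on", values="value", aggfunc="first"
    )
    return mat


def plot_heatmap(
    act: ActivitySeries,
    schedule: LightSchedule,
    out_path: str | Path,
    vmax: float | None = None,
) -> pd.DataFrame:
    """Activity heatmap (rows = days, cols = minutes post lights-on).

    The lights-off half of the day is annotated with a band.  Returns the
    plotted matrix, which is also written as a ``.csv`` sidecar.
    """
    mat = activity_day_matrix(act, schedule)
    if mat.empty:
        raise ValueError("need at least one day of activity")
    out_path = Path(out_path)
    fig, ax = plt.subplots(figsize=(10, max(2, 0.25 * len(mat))))
    im = ax.imshow(
        mat.to_numpy(),
        aspect="auto",
        interpolation="none",
        cmap="viridis",
        vmin=0.0,
        vmax=vmax,
    )
    dark_start = schedule.phase_length_hours * 60
    ax.axvline(dark_start, color="white", lw=1.0, ls="--")
    ax.set_xlabel("minute post lights-on")
    ax.set_ylabel("day")
    ax.set_yticks(range(len(mat)))
    ax.set_yticklabels([str(d) for d in mat.index], fontsize=6)
    ax.set_title(f"cage {act.cage_id} minute activity")
    fig.colorbar(im, ax=ax, label="activity index")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    mat.to_csv(out_path.with_suffix(".csv"))
    return mat


def plot_phase_bars(
    group_summary: pd.DataFrame, metric: str, out_path: str | Path
) -> pd.DataFrame:
    """Grouped bars of a phase metric by sex×genotype (weekly-mean summary)."""
    sel = group_summary[group_summary["metric"] == metric]
    if sel.empty:
        raise ValueError(f"metric {metric!r} not present in summary")
    out_path = Path(out_path)
    pivot = sel.pivot_table(
        index=["sex", "genotype"], columns="phase", values="value"
    )
    ax = pivot.plot.bar(figsize=(7, 4))
    ax.set_ylabel(metric)
    ax.figure.tight_layout()
    ax.figure.savefig(out_path, dpi=120)
    plt.close(ax.figure)
    pivot.to_csv(out_path.with_suffix(".csv"))
    return pivot


def plot_hourly_pct_zero(
    hourly: pd.DataFrame, design: pd.DataFrame, out_path: str | Path
) -> pd.DataFrame:
    """Mean percent-zero per hour post lights-on, one line per group."""
    df = hourly.merge(design, on="cage_id", how="left")
    g = (
        df.groupby(["sex", "genotype", "hour_post_lights_on"], sort=True)["value"]
        .mean()
        .reset_index()
    )
    out_path = Path(out_path)
    fig, ax = plt.subplots(figsize=(8, 4))
    for (sex, gen), gg in g.groupby(["sex", "genotype"], sort=True):
        ax.plot(gg["hour_post_lights_on"], gg["value"], label=f"{sex}/{gen}")
    ax.axvspan(12, 24, color="0.85", zorder=0)
    ax.set_xlabel("hour post lights-on")
    ax.set_ylabel("% time at zero activity")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    g.to_csv(out_path.with_suffix(".csv"), index=False)
    return g


def plot_bout_histogram(
    bout_summary: pd.DataFrame, design: pd.DataFrame, phase: str, out_path: str | Path
) -> pd.DataFrame:
    """Group-mean time-weighted bout-duration histogram for one phase."""
    df = bout_summary.merge(design, on="cage_id", how="left")
    sel = df[
        (df["phase"] == phase) & df["metric"].str.startswith("bout_weight")
    ]
    if sel.empty:
        raise ValueError(f"no bout weights for phase {phase}")
    g = (
        sel.groupby(["sex", "genotype", "metric"], sort=True)["value"]
        .mean()
        .reset_index()
    )
    out_path = Path(out_path)
    pivot = g.pivot_table(index="metric", columns=["sex", "genotype"], values="value")
    ax = pivot.plot.bar(figsize=(7, 4))
    ax.set_ylabel("share of rest time")
    ax.set_title(f"{phase} phase rest-bout durations")
    ax.figure.tight_layout()
    ax.figure.savefig(out_path, dpi=120)
    plt.close(ax.figure)
    pivot.to_csv(out_path.with_suffix(".csv"))
    return pivot
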