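"""Zero-activity (rest) analytics.

Everything here runs on the binary per-second immobility signal or the
per-minute activity index of a single cage:

* hourly percent of zero activity across the 24 h post lights-on;
* the least active consecutive hour of each day (the 60 consecutive
  minutes with the lowest mean activity) and where in the day it falls;
* rest bouts — maximal runs of immobility of at least 40 s, the standard
  behavioural proxy for sleep in group-housed mice;
* time-weighted bout-duration histograms (<5 min, 5–15 min, >15 min) and
  the fraction of rest time spent in bouts longer than 30 min.

Masked seconds terminate immobility runs: a sensor gap is never bridged
into a rest bout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import DARK, LIGHT, ActivitySeries, ImmobilitySeries, LightSchedule
from .phases import assign_phases, phase_of

MINUTES_PER_DAY = 1440
WINDOW_MIN = 60
MAX_MASKED_IN_WINDOW = 10


def _hourly_counts(imm: ImmobilitySeries, schedule: LightSchedule) -> pd.DataFrame:
    """Immobile/unmasked/total second counts per (day, hour post lights-on)."""
    ts = imm.timestamps()
    on_offset = pd.Timedelta(
        hours=schedule.lights_on.hour, minutes=schedule.lights_on.minute
    )
    shifted = pd.DatetimeIndex(ts) - on_offset
    sec = shifted.asi8 // 1_000_000_000
    day_idx = sec // 86400
    hour = (sec % 86400) // 3600
    day0 = int(day_idx.min())
    code = (day_idx - day0) * 24 + hour
    n_codes = int(code.max()) + 1
    ok = (~imm.mask).astype(float)
    imm_ok = imm.values * ok
    counts = pd.DataFrame(
        {
            "code": np.arange(n_codes),
            "immobile_s": np.bincount(code, weights=imm_ok, minlength=n_codes),
            "ok_s": np.bincount(code, weights=ok, minlength=n_codes),
            "n_s": np.bincount(code, minlength=n_codes),
        }
    )
    counts["day"] = pd.to_datetime((day0 + counts["code"] // 24) * 86400 * 10**9)
    counts["hour_post_lights_on"] = counts["code"] % 24
    light_hours = int(schedule.phase_length_hours)
    counts["phase"] = np.where(
        counts["hour_post_lights_on"] < light_hours, LIGHT, DARK
    )
    return counts.drop(columns="code")


def percent_zero_per_hour(
    imm: ImmobilitySeries, schedule: LightSchedule
) -> pd.DataFrame:
    """Percent of unmasked seconds at zero activity, per hour post lights-on.

    Tidy output: cage_id, day, hour_post_lights_on (0..23), phase, value.
    Hours with no unmasked second are omitted.
    """
    g = _hourly_counts(imm, schedule)
    g = g[g["ok_s"] > 0].copy()
    g["value"] = 100.0 * g["immobile_s"] / g["ok_s"]
    g.insert(0, "cage_id", imm.cage_id)
    return g[["cage_id", "day", "hour_post_lights_on", "phase", "value"]].reset_index(
        drop=True
    )


def least_active_hour(
    act: ActivitySeries, schedule: LightSchedule
) -> pd.DataFrame:
    """The 60 consecutive minutes with the lowest mean activity, per day.

    The search scans all 1381 window starts within the lights-on-anchored
    day (windows never wrap into the next day); window means ignore masked
    minutes, windows with more than 10 masked minutes are skipped; ties are
    broken by the earliest start.  Tidy output: cage_id, day, start_minute
    (offset from lights-on), mean_activity, phase_of_start.
    """
    labels = assign_phases(act.timestamps(), schedule)
    df = labels.assign(activity=act.values)
    dark_start = int(schedule.phase_length_hours * 60)
    rows = []
    for day, g in df.groupby("day", sort=True):
        if len(g) != MINUTES_PER_DAY:
            continue  # incomplete day at a recording edge
        x = g["activity"].to_numpy()
        good = np.isfinite(x)
        xz = np.where(good, x, 0.0)
        # direct window sums: exact ties stay exact (cumsum differencing
        # would break the earliest-start tie rule via cancellation noise)
        win = np.lib.stride_tricks.sliding_window_view(xz, WINDOW_MIN)
        sums = win.sum(axis=1)
        goods = np.lib.stride_tricks.sliding_window_view(
            good.astype(np.int64), WINDOW_MIN
        ).sum(axis=1)
        valid = goods >= WINDOW_MIN - MAX_MASKED_IN_WINDOW
        if not valid.any():
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(valid, sums / np.maximum(goods, 1), np.inf)
        start = int(np.argmin(means))  # argmin returns the earliest tie
        rows.append(
            {
                "cage_id": act.cage_id,
                "day": day,
                "start_minute": start,
                "mean_activity": float(means[start]),
                "phase_of_start": LIGHT if start < dark_start else DARK,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cage_id", "day", "start_minute", "mean_activity", "phase_of_start"],
    )


def least_active_hour_histogram(
    results: pd.DataFrame, bin_minutes: int = 60
) -> tuple[pd.DataFrame, float]:
    """Histogram of least-active-hour start times + fraction starting in DARK.

    ``results`` is the output of :func:`least_active_hour`, possibly pooled
    over cages/groups.  Returns (counts per start-time bin, dark fraction).
    """
    if results.empty:
        raise ValueError("need at least one least-active-hour result")
    edges = np.arange(0, MINUTES_PER_DAY + bin_minutes, bin_minutes)
    counts, _ = np.histogram(results["start_minute"].to_numpy(), bins=edges)
    hist = pd.DataFrame(
        {"bin_start_minute": edges[:-1], "count": counts.astype(int)}
    )
    dark_fraction = float((results["phase_of_start"] == DARK).mean())
    return hist, dark_fraction


def detect_rest_bouts(
    imm: ImmobilitySeries,
    schedule: LightSchedule,
    bout_min: int = 40,
    split_at_phase_boundary: bool = False,
) -> pd.DataFrame:
    """Maximal immobility runs of at least ``bout_min`` seconds.

    A bout's phase is the phase of its onset second (a bout straddling the
    light/dark boundary counts once, to its onset phase) unless
    ``split_at_phase_boundary`` is set, in which case runs are cut at phase
    transitions before thresholding.  Masked seconds always break runs.
    Tidy output: cage_id, start (timestamp), day, duration_s, phase.
    """
    active = (imm.values == 1) & ~imm.mask
    if split_at_phase_boundary:
        ph = phase_of(imm.timestamps(), schedule)
        breaks = np.empty(len(active), dtype=bool)
        breaks[0] = False
        breaks[1:] = ph[1:] != ph[:-1]
    else:
        breaks = np.zeros(len(active), dtype=bool)

    # run starts: immobile here, and (not immobile before, or a forced break)
    prev = np.concatenate(([False], active[:-1]))
    is_start = active & (~prev | breaks)
    starts = np.flatnonzero(is_start)
    if starts.size == 0:
        return pd.DataFrame(
            columns=["cage_id", "start", "day", "duration_s", "phase"]
        )
    # run ends: immobile here, and (not immobile after, or break at next)
    nxt = np.concatenate((active[1:], [False]))
    brk_next = np.concatenate((breaks[1:], [False]))
    is_end = active & (~nxt | brk_next)
    ends = np.flatnonzero(is_end)
    durations = ends - starts + 1

    keep = durations >= bout_min
    starts, durations = starts[keep], durations[keep]
    ts = imm.timestamps()
    onset = ts[starts]
    labels = assign_phases(onset, schedule)
    return pd.DataFrame(
        {
            "cage_id": imm.cage_id,
            "start": onset,
            "day": labels["day"].to_numpy(),
            "duration_s": durations.astype(int),
            "phase": labels["phase"].to_numpy(),
        }
    )


def _bin_labels(edges_min: tuple[float, ...]) -> list[str]:
    labels = [f"<{edges_min[0]:g}min"]
    labels += [f"{a:g}-{b:g}min" for a, b in zip(edges_min, edges_min[1:])]
    labels.append(f">{edges_min[-1]:g}min")
    return labels


def time_weighted_histogram(
    bouts: pd.DataFrame,
    phase: str,
    edges_min: tuple[float, ...] = (5.0, 15.0),
) -> pd.DataFrame:
    """Share of total rest time per duration bin, within one phase.

    Bins are [bout_min, e1), [e1, e2), ..., [e_last, inf) in minutes, and
    each bout contributes its *duration* (time-weighting), normalised by
    the phase's total rest time so weights sum to 1.  With no bout in the
    phase all weights are 0 and the flag column says so.
    """
    labels = _bin_labels(edges_min)
    sel = bouts.loc[bouts["phase"] == phase, "duration_s"].to_numpy(dtype=float)
    edges_s = np.array([0.0, *[e * 60 for e in edges_min], np.inf])
    sums = np.array(
        [sel[(sel >= lo) & (sel < hi)].sum() for lo, hi in zip(edges_s, edges_s[1:])]
    )
    total = sums.sum()
    weights = sums / total if total > 0 else np.zeros_like(sums)
    return pd.DataFrame(
        {
            "phase": phase,
            "bin": labels,
            "weight": weights,
            "flag": "ok" if total > 0 else "empty",
        }
    )


def long_bout_fraction(
    bouts: pd.DataFrame, phase: str, threshold_min: float = 30.0
) -> float:
    """Fraction of a phase's rest time spent in bouts longer than the threshold."""
    sel = bouts.loc[bouts["phase"] == phase, "duration_s"].to_numpy(dtype=float)
    total = sel.sum()
    if total == 0:
        return 0.0
    return float(sel[sel > threshold_min * 60].sum() / total)
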