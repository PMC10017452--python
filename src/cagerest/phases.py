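"""Calendar logic: light/dark phase labels, lights-on-anchored days, day
exclusion around cage changes, and weekly aggregation.

A "day" here runs lights-on to lights-on (07:00 by default), not midnight to
midnight, so that hour 0 post lights-on is the first light hour and hour 12
the first dark hour.  Hourly plots and the least-active-hour search are all
phase-anchored this way.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .datamodel import DARK, LIGHT, CageMetadata, LightSchedule

logger = logging.getLogger(__name__)


def phase_of(timestamps: pd.DatetimeIndex | pd.Series, schedule: LightSchedule) -> np.ndarray:
    """Label each timestamp LIGHT or DARK (half-open [lights_on, lights_off))."""
    ts = pd.DatetimeIndex(timestamps)
    tod = ts.hour * 3600 + ts.minute * 60 + ts.second
    on = schedule.lights_on.hour * 3600 + schedule.lights_on.minute * 60
    off = schedule.lights_off.hour * 3600 + schedule.lights_off.minute * 60
    return np.where((tod >= on) & (tod < off), LIGHT, DARK)


def assign_phases(
    timestamps: pd.DatetimeIndex | pd.Series, schedule: LightSchedule
) -> pd.DataFrame:
    """Phase, lights-on-anchored date and hour-post-lights-on per timestamp.

    Returns a DataFrame with columns:

    ``phase``
        LIGHT or DARK.
    ``day``
        calendar date of the lights-on instant that opened the current
        24-h analysis day.
    ``hour_post_lights_on``
        integer 0..23; hour 0 starts at lights-on, hour 12 at lights-off.
    ``minute_post_lights_on``
        integer 0..1439.
    """
    ts = pd.DatetimeIndex(timestamps)
    on_offset = pd.Timedelta(
        hours=schedule.lights_on.hour, minutes=schedule.lights_on.minute
    )
    shifted = ts - on_offset
    day = shifted.normalize()
    sec_into_day = (shifted.asi8 - day.asi8) // 1_000_000_000
    light_len = int(schedule.phase_length_hours * 3600)
    return pd.DataFrame(
        {
            "phase": np.where(sec_into_day < light_len, LIGHT, DARK),
            "day": day,
            "hour_post_lights_on": sec_into_day // 3600,
            "minute_post_lights_on": sec_into_day // 60,
        },
        index=ts,
    )


def exclude_days(table: pd.DataFrame, metadata: dict[str, CageMetadata] | list[CageMetadata]) -> pd.DataFrame:
    """Drop all rows whose analysis day falls on a cage-change date.

    ``table`` must carry ``cage_id`` and ``day`` (date) columns.  Removal is
    logged per cage; the operation is idempotent.  If nothing survives, a
    warning is raised and an empty table returned.
    """
    if isinstance(metadata, list):
        metadata = {m.cage_id: m for m in metadata}
    if table.empty:
        return table
    drop = np.zeros(len(table), dtype=bool)
    days = pd.to_datetime(pd.Series(table["day"].values))
    for cage_id, meta in metadata.items():
        if not meta.cage_change_dates:
            continue
        change = pd.to_datetime(sorted(meta.cage_change_dates))
        hit = (table["cage_id"].values == cage_id) & days.isin(change).values
        n = int(hit.sum())
        if n:
            logger.info("cage %s: excluding %d rows on cage-change days", cage_id, n)
        drop |= hit
    out = table.loc[~drop].reset_index(drop=True)
    if out.empty:
        warnings.warn("all days excluded as cage-change days", stacklevel=2)
    return out


def add_week_index(table: pd.DataFrame, start_day=None) -> pd.DataFrame:
    """Attach a 1-based week index (week 1 = first 7 recording days)."""
    out = table.copy()
    days = pd.to_datetime(out["day"])
    if start_day is None:
        start_day = days.min()
    else:
        start_day = pd.Timestamp(start_day)
    out["week"] = ((days - start_day).dt.days // 7) + 1
    return out


def weekly_aggregate(table: pd.DataFrame, start_day=None) -> pd.DataFrame:
    """Per-cage, per-week, per-phase, per-metric means over included days.

    ``table`` is tidy with columns cage_id, day, phase, metric, value.  Weeks
    with zero included days simply yield no row; callers that need a
    complete grid should reindex and treat the hole as missing.
    """
    t = add_week_index(table, start_day=start_day)
    grouped = (
        t.groupby(["cage_id", "week", "phase", "metric"], sort=True)["value"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "value", "count": "n_days"})
    )
    return grouped
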