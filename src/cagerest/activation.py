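"""Capacitance → activity conversion.

An electrode counts as *activated* in a comparison window when the absolute
difference between two consecutive capacitance measurements exceeds a fixed
threshold λ chosen to separate sensor noise from animal movement.  Two
thresholds are used for two purposes:

* the standard λ yields the graded per-minute activity index (activation
  density: activated (electrode, window) pairs over all unmasked pairs in
  the minute);
* the lowest usable λ (1.25, applied to consecutive 1-s average windows)
  yields the binary per-second immobility signal — a second is immobile
  only if *no* electrode moved, i.e. both mice are still.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ActivitySeries, CapacitanceRecord, ImmobilitySeries, N_ELECTRODES


@dataclass
class ActivationMatrix:
    """Binary activations: rows = consecutive-sample comparisons, cols = electrodes."""

    cage_id: str
    start_time: pd.Timestamp
    fs: float
    values: np.ndarray  # (n-1, 12) bool
    mask: np.ndarray  # (n-1,) bool, True = comparison involves a masked sample


def detect_activations(record: CapacitanceRecord, lam: float) -> ActivationMatrix:
    """Threshold consecutive capacitance differences at λ per electrode.

    One output row per consecutive sample pair; a comparison touching a
    masked sample is itself masked.
    """
    if lam <= 0:
        raise ValueError("activation threshold must be positive")
    if record.n_samples < 2:
        raise ValueError("need at least two samples to compare")
    diffs = np.abs(np.diff(record.values, axis=0))
    acts = diffs > lam
    mask = record.mask[:-1] | record.mask[1:]
    acts[mask] = False
    return ActivationMatrix(
        cage_id=record.cage_id,
        start_time=record.start_time,
        fs=record.fs,
        values=acts,
        mask=mask,
    )


def activity_index(
    acts: ActivationMatrix, smooth_window: int | None = None
) -> ActivitySeries:
    """Per-minute activation density, optionally smoothed.

    Raw value for a minute = activated (comparison, electrode) pairs divided
    by unmasked pairs in that minute — 2880 pairs at 4 Hz (240 comparisons x
    12 electrodes).  A fully-masked minute is NaN.  ``smooth_window`` > 1
    applies a centred moving average over that many minutes (NaN-aware).
    """
    per_min = int(round(60 * acts.fs))
    n_min = acts.values.shape[0] // per_min
    if n_min == 0:
        raise ValueError("record shorter than one minute")
    v = acts.values[: n_min * per_min].reshape(n_min, per_min, N_ELECTRODES)
    m = acts.mask[: n_min * per_min].reshape(n_min, per_min)
    activated = v.sum(axis=(1, 2)).astype(float)
    denom = (per_min - m.sum(axis=1)).astype(float) * N_ELECTRODES
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(denom > 0, activated / np.maximum(denom, 1), np.nan)
    raw[denom == 0] = np.nan

    values = raw
    if smooth_window is not None and smooth_window > 1:
        values = (
            pd.Series(raw)
            .rolling(smooth_window, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )
    # first full minute starts at the record start (comparison i covers
    # samples i, i+1, attributed to the minute of sample i)
    return ActivitySeries(
        cage_id=acts.cage_id, start_time=acts.start_time, values=values
    )


def immobility_series(
    record: CapacitanceRecord, lambda_immobility: float = 1.25
) -> ImmobilitySeries:
    """Per-second binary immobility from consecutive 1-s average windows.

    For each second s (s >= 1): average the capacitance per electrode over
    second s-1 and second s; the second is immobile (1) iff no electrode's
    average moved by more than λ.  The first second has no predecessor and
    is dropped.  A second touching masked samples is masked.
    """
    if lambda_immobility <= 0:
        raise ValueError("immobility threshold must be positive")
    per_sec = int(round(record.fs))
    if per_sec < 1:
        raise ValueError("need fs >= 1 Hz for 1-s averages")
    n_sec = record.n_samples // per_sec
    if n_sec < 2:
        raise ValueError("record shorter than two seconds")
    v = record.values[: n_sec * per_sec].reshape(n_sec, per_sec, N_ELECTRODES)
    m = record.mask[: n_sec * per_sec].reshape(n_sec, per_sec)
    sec_mask = m.any(axis=1)
    with np.errstate(invalid="ignore"):
        sec_means = np.nanmean(np.where(m[:, :, None], np.nan, v), axis=1)
    diffs = np.abs(sec_means[1:] - sec_means[:-1])
    out_mask = sec_mask[1:] | sec_mask[:-1]
    with np.errstate(invalid="ignore"):
        immobile = (np.nan_to_num(diffs, nan=np.inf) <= lambda_immobility).all(axis=1)
    immobile[out_mask] = 0
    return ImmobilitySeries(
        cage_id=record.cage_id,
        start_time=record.start_time + pd.Timedelta(seconds=1),
        values=immobile.astype(np.int8),
        mask=out_mask,
    )
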