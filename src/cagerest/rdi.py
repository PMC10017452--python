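"""Regularity Disruption Index (RDI).

RDI quantifies how fragmented the minute-by-minute activity pattern of a
cage is within a 12-h light or dark phase.  It is the sample entropy of the
band-pass-filtered minute activity series: a phase in which all minutes
look alike (consolidated rest, or steady activity) gives an RDI near 0; a
phase where successive minutes keep differing (fragmented rest/activity)
gives a high RDI.

Sample entropy is SampEn(m, r) = −ln(A/B), where B counts pairs of length-m
templates within Chebyshev distance r of each other, A the same for length
m+1, with self-matches excluded; both counts run over the first N−m
template positions (the Richman–Moorman convention).  The tolerance r is
expressed as a fraction of the SD of the *filtered* phase segment, so LIGHT
and DARK are self-normalised and the index is invariant to affine rescaling
of the activity values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .datamodel import ActivitySeries, AnalysisConfig, LightSchedule
from .phases import assign_phases

OK = "ok"
LOW_CONFIDENCE = "low_confidence"
UNDEFINED = "undefined"
CAPPED = "capped"

_CONSTANT_SD_EPS = 1e-12


def bandpass_sos(
    band_low_period: float, band_high_period: float, order: int
) -> np.ndarray:
    """Butterworth band-pass sections for a 1 sample/min series.

    Periods are in minutes; the passband covers frequencies between
    1/band_high_period and 1/band_low_period cycles per minute.  The short
    period must exceed 2 min (the Nyquist period at this sampling rate).
    """
    if band_low_period <= 2.0:
        raise ValueError(
            "short-period passband edge must exceed 2 min "
            "(Nyquist period at 1 sample/min)"
        )
    nyq = 0.5  # cycles/min
    wn = (1.0 / band_high_period / nyq, 1.0 / band_low_period / nyq)
    return signal.butter(order, wn, btype="bandpass", output="sos")


def bandpass_filter(
    series: np.ndarray,
    band_low_period: float = 2.5,
    band_high_period: float = 120.0,
    order: int = 2,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of a minute-resolution series.

    Forward-backward filtering (``sosfiltfilt``) gives zero phase shift and
    squares the one-pass magnitude response; DC is removed entirely.
    Output length equals input length.
    """
    x = np.asarray(series, dtype=float)
    sos = bandpass_sos(band_low_period, band_high_period, order)
    # sosfiltfilt needs padding room: default padlen for these sections
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.size <= padlen:
        raise ValueError(
            f"series of length {x.size} too short for order-{order} "
            f"zero-phase filtering (need > {padlen})"
        )
    return signal.sosfiltfilt(sos, x)


def sample_entropy(
    series: np.ndarray, m: int = 2, r: float = 0.2, return_counts: bool = False
):
    """SampEn(m, r) of a numeric sequence; NaN when no template pair matches.

    ``r`` is an absolute Chebyshev tolerance here (callers scale it by the
    segment SD).  Degenerate cases: B = 0 → NaN (undefined); A = 0 with
    B > 0 → the capped estimate −ln(1/(B+1)), avoiding infinities.
    With ``return_counts`` the raw pair counts (A, B) are also returned.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    if n <= m + 1:
        raise ValueError(f"series length {n} must exceed m+1 = {m + 1}")

    # Chebyshev distance between length-k templates via running elementwise max
    d = np.abs(x[:, None] - x[None, :])
    n_t = n - m  # number of template positions for both lengths
    cm = d[:n_t, :n_t].copy()
    for k in range(1, m):
        np.maximum(cm, d[k : k + n_t, k : k + n_t], out=cm)
    cm1 = np.maximum(cm, d[m : m + n_t, m : m + n_t])

    iu = np.triu_indices(n_t, k=1)  # exclude self-matches
    b = int((cm[iu] <= r).sum())
    a = int((cm1[iu] <= r).sum())

    if b == 0:
        value = np.nan
    elif a == 0:
        value = -np.log(1.0 / (b + 1))
    else:
        value = -np.log(a / b)
    if return_counts:
        return value, a, b
    return value


@dataclass(frozen=True)
class RdiResult:
    cage_id: str
    day: object  # datetime.date
    phase: str
    rdi: float
    flag: str


def _phase_rdi(segment: np.ndarray, cfg: AnalysisConfig) -> tuple[float, str]:
    """RDI of one phase segment of minute activity (NaN = masked minute)."""
    x = np.asarray(segment, dtype=float)
    masked_frac = float(np.isnan(x).mean())
    flag = OK if masked_frac <= cfg.max_masked_fraction else LOW_CONFIDENCE
    if masked_frac == 1.0:
        return np.nan, UNDEFINED
    if np.isnan(x).any():
        # interior gaps interpolated so the filter sees a contiguous series
        idx = np.arange(x.size)
        good = ~np.isnan(x)
        x = np.interp(idx, idx[good], x[good])
    y = bandpass_filter(
        x, cfg.band_low_period, cfg.band_high_period, cfg.filter_order
    )
    sd = float(np.std(y))
    if sd < _CONSTANT_SD_EPS:
        return 0.0, flag  # (near-)constant filtered series: perfectly regular
    value, a, b = sample_entropy(
        y, m=cfg.samp_en_m, r=cfg.samp_en_r * sd, return_counts=True
    )
    if b == 0:
        return np.nan, UNDEFINED
    if a == 0:
        return value, CAPPED
    return value, flag


def compute_rdi(
    series: ActivitySeries,
    schedule: LightSchedule,
    cfg: AnalysisConfig,
) -> pd.DataFrame:
    """RDI per (cage, lights-on-anchored day, phase).

    Only complete 720-minute phase segments are scored; partial segments at
    the edges of the recording are dropped.  Returns a tidy frame with
    columns cage_id, day, phase, rdi, flag.
    """
    labels = assign_phases(series.timestamps(), schedule)
    df = labels.assign(activity=series.values)
    rows = []
    expected = int(schedule.phase_length_hours * 60)
    for (day, phase), g in df.groupby(["day", "phase"], sort=True):
        if len(g) != expected:
            continue
        rdi, flag = _phase_rdi(g["activity"].to_numpy(), cfg)
        rows.append(
            {
                "cage_id": series.cage_id,
                "day": day,
                "phase": phase,
                "rdi": rdi,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows, columns=["cage_id", "day", "phase", "rdi", "flag"])
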