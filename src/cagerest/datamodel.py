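"""Domain types shared by every stage of the home-cage analysis pipeline.

The experimental unit throughout is the *cage* (two co-housed mice of the
same sex and genotype), never the individual animal.  Two parallel
"currencies" are derived from the raw capacitance signal:

* :class:`ActivitySeries` — a graded per-minute activity index in [0, 1]
  (activation density: the fraction of (electrode, sample-pair) comparisons
  whose capacitance difference exceeds a threshold).
* :class:`ImmobilitySeries` — a per-second binary series where 1 means no
  electrode detected any movement in that second, i.e. both mice immobile.

Missing sensor samples are *masked*, never zero-filled: a fabricated zero
would be indistinguishable from rest, which is the phenotype under study.
All downstream metrics receive the mask and renormalise their denominators.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

N_ELECTRODES = 12

LIGHT = "LIGHT"
DARK = "DARK"

GENOTYPES = ("WT", "MUT")
SEXES = ("M", "F")


class FormatError(ValueError):
    """An input file does not match the expected layout."""


class DataError(ValueError):
    """Input data violate an invariant (e.g. non-monotone timestamps)."""


@dataclass(frozen=True)
class LightSchedule:
    """A 12:12 light/dark cycle.

    The two phases partition every 24-h day.  Intervals are half-open:
    a sample at exactly ``lights_off`` belongs to DARK.
    """

    lights_on: dt.time = dt.time(7, 0)
    lights_off: dt.time = dt.time(19, 0)

    def __post_init__(self) -> None:
        if self.lights_on >= self.lights_off:
            raise ValueError("lights_on must precede lights_off within the day")

    @property
    def phase_length_hours(self) -> float:
        on = self.lights_on.hour * 3600 + self.lights_on.minute * 60 + self.lights_on.second
        off = self.lights_off.hour * 3600 + self.lights_off.minute * 60 + self.lights_off.second
        return (off - on) / 3600.0


@dataclass(frozen=True)
class CageMetadata:
    cage_id: str
    genotype: str  # "WT" | "MUT"
    sex: str  # "M" | "F"
    cohort_id: str = "C1"
    n_animals: int = 2
    cage_change_dates: frozenset[dt.date] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}, got {self.genotype!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.n_animals != 2:
            raise ValueError("study design houses exactly two mice per cage")
        object.__setattr__(self, "cage_change_dates", frozenset(self.cage_change_dates))


@dataclass
class CapacitanceRecord:
    """Raw per-electrode capacitance for one cage on a regular time grid.

    ``values`` has one row per sample and exactly 12 electrode columns.
    ``mask`` is True where the sample is missing (sensor gap); masked rows
    carry NaN in ``values``.
    """

    cage_id: str
    start_time: pd.Timestamp
    fs: float  # Hz
    values: np.ndarray  # (n, 12) float
    mask: np.ndarray | None = None  # (n,) bool, True = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_ELECTRODES:
            raise FormatError(
                f"capacitance matrix must have {N_ELECTRODES} electrode columns, "
                f"got shape {self.values.shape}"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.mask is None:
            self.mask = np.zeros(len(self.values), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (len(self.values),):
            raise ValueError("mask must be one flag per sample row")

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def timestamps(self) -> pd.DatetimeIndex:
        step = pd.Timedelta(seconds=1.0 / self.fs)
        return pd.date_range(self.start_time, periods=self.n_samples, freq=step)


@dataclass
class ActivitySeries:
    """Per-minute graded activity index for one cage; NaN = masked minute."""

    cage_id: str
    start_time: pd.Timestamp
    values: np.ndarray  # (n_minutes,) float in [0, 1] or NaN
    resolution: pd.Timedelta = pd.Timedelta(minutes=1)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("activity index must lie in [0, 1]")

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=len(self.values), freq=self.resolution)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"timestamp": self.timestamps(), "cage_id": self.cage_id, "activity": self.values}
        )


@dataclass
class ImmobilitySeries:
    """Per-second binary immobility for one cage (1 = both mice immobile)."""

    cage_id: str
    start_time: pd.Timestamp
    values: np.ndarray  # (n_seconds,) int8 in {0, 1}
    mask: np.ndarray | None = None  # True = missing second
    resolution: pd.Timedelta = pd.Timedelta(seconds=1)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("immobility values must be binary")
        if self.mask is None:
            self.mask = np.zeros(len(self.values), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask must match values in length")

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=len(self.values), freq=self.resolution)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps(),
                "cage_id": self.cage_id,
                "immobile": self.values,
                "masked": self.mask.astype(int),
            }
        )


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable analysis parameters, with study defaults.

    ``lambda_immobility`` (1.25, comparing consecutive 1-s average windows)
    is the lowest usable electrode-activation threshold and defines the
    binary immobility signal; ``lambda_standard`` is the ordinary activation
    threshold behind the graded activity index (the vendor value is
    unpublished; only its order relative to ``lambda_immobility`` matters).
    Sample-entropy settings (m, r) follow the standard conventions m=2,
    r = 0.2 x SD.  The Butterworth passband keeps bout-scale structure
    (periods between ``band_low_period`` and ``band_high_period`` minutes)
    while removing DC and circadian trend.
    """

    lambda_standard: float = 5.0
    lambda_immobility: float = 1.25
    smooth_window: int = 3  # minutes, centred moving average
    samp_en_m: int = 2
    samp_en_r: float = 0.2  # tolerance as a fraction of the series SD
    band_low_period: float = 2.5  # minutes (short-period passband edge)
    band_high_period: float = 120.0  # minutes (long-period passband edge)
    filter_order: int = 2
    bout_min: int = 40  # seconds
    bout_bins: tuple[float, ...] = (5.0, 15.0)  # interior bin edges, minutes
    long_bout_threshold: float = 30.0  # minutes
    max_masked_fraction: float = 0.2  # above this a phase RDI is low-confidence
    split_bouts_at_phase_boundary: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bout_min <= 0:
            raise ValueError("bout_min must be positive")
        edges = tuple(self.bout_bins)
        if any(b >= a for b, a in zip(edges, edges[1:])):
            raise ValueError("bout bin edges must be strictly increasing")
        if not (0 < self.band_low_period < self.band_high_period):
            raise ValueError("require 0 < band_low_period < band_high_period")
        if self.samp_en_r <= 0:
            raise ValueError("sample-entropy tolerance must be positive")


def with_overrides(cfg: AnalysisConfig, **kwargs) -> AnalysisConfig:
    """Return a copy of ``cfg`` with selected fields replaced."""
    return replace(cfg, **kwargs)
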