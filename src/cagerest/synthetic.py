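"""Synthetic home-cage cohort generator.

Each cage is a two-state (REST / ACTIVE) semi-Markov process at 1-s
resolution: the cage alternates between rest bouts and activity bouts with
log-normal dwell times whose means depend on light/dark phase, genotype and
an hourly circadian profile.  REST seconds emit immobility = 1; each
minute's activity index is the minute's ACTIVE fraction times a group
activity amplitude plus clipped Gaussian noise.  The generator reproduces
the study conditions: two mice per cage (the cage is the unit), a 12:12
light cycle with lights on 07:00–19:00, 5 weeks of continuous recording,
nocturnal activity that is higher in control females than males, weekly
cage-change days, and a mutant phenotype of reduced activity with longer
dark-phase rest bouts (dark rest-dwell mean doubled, activity amplitude
reduced).

Log-normal dwells give the heavy-tailed bout-duration mix that spans the
<5 / 5–15 / >15 / >30-min analysis bins.  Every cage's output is a pure
function of (params, cage spec, seed).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import (
    DARK,
    LIGHT,
    ActivitySeries,
    CageMetadata,
    CapacitanceRecord,
    ImmobilitySeries,
    LightSchedule,
    N_ELECTRODES,
)

SECONDS_PER_DAY = 86400

#: hourly multiplier on the mean ACTIVE dwell, hour 0 = lights-on.
#: Light hours are rest-dominated; dark hours carry the activity, with
#: crepuscular peaks just after lights-off and before lights-on and a
#: mid-dark "nap" dip (hours 17-19) during which mice rest substantially —
#: the feature that lets the least active hour occasionally fall in the
#: dark, as observed in real home-cage data.
DEFAULT_CIRCADIAN_PROFILE = (
    # light phase, hours 0-11
    0.7, 0.6, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.6, 0.6, 0.7, 0.9,
    # dark phase, hours 12-23
    1.8, 1.6, 1.2, 0.9, 0.5, 0.22, 0.18, 0.25, 0.8, 1.2, 1.5, 1.7,
)

#: default cages per (sex, genotype) cell, matching the study's group sizes
DEFAULT_N_CAGES = {("M", "WT"): 10, ("M", "MUT"): 10, ("F", "WT"): 11, ("F", "MUT"): 8}


@dataclass(frozen=True)
class SimulationParams:
    """Full generative specification of a cohort."""

    n_cages: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_N_CAGES)
    )
    weeks: int = 5
    start_date: dt.date = dt.date(2021, 3, 1)  # a Monday
    schedule: LightSchedule = field(default_factory=LightSchedule)
    circadian_profile: tuple[float, ...] = DEFAULT_CIRCADIAN_PROFILE
    # mean dwell times in seconds, baseline (WT male) group
    dwell_rest_light: float = 300.0
    dwell_active_light: float = 120.0
    dwell_rest_dark: float = 110.0
    dwell_active_dark: float = 260.0
    dwell_sigma: float = 1.0  # log-normal shape (SD of log dwell)
    day_effect_sigma: float = 0.3  # day-to-day log-normal spread of rest dwells
    activity_level: float = 0.25  # mean minute activity while fully ACTIVE
    activity_noise_sd: float = 0.03
    # group effects (multiplicative)
    genotype_rest_dark_mult: float = 2.0  # MUT dark rest-dwell mean
    genotype_activity_mult: float = 0.7  # MUT activity amplitude
    sex_activity_mult: float = 1.25  # female activity amplitude
    cage_change_weekday: int = 0  # Monday, weekly
    emit_capacitance: bool = False
    capacitance_noise_sd: float = 0.3  # sub-threshold jitter, immobile seconds
    capacitance_jump: float = 8.0  # supra-threshold jumps, active seconds
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.circadian_profile) != 24:
            raise ValueError("circadian profile needs 24 hourly multipliers")
        if min(self.circadian_profile) <= 0:
            raise ValueError("circadian multipliers must be positive")
        for name in (
            "dwell_rest_light",
            "dwell_active_light",
            "dwell_rest_dark",
            "dwell_active_dark",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.weeks < 1:
            raise ValueError("need at least one week")

    def dwell_means(self, genotype: str) -> dict[str, tuple[float, float]]:
        """(rest, active) mean dwell per phase for a genotype."""
        rest_dark = self.dwell_rest_dark * (
            self.genotype_rest_dark_mult if genotype == "MUT" else 1.0
        )
        return {
            LIGHT: (self.dwell_rest_light, self.dwell_active_light),
            DARK: (rest_dark, self.dwell_active_dark),
        }

    def amplitude(self, sex: str, genotype: str) -> float:
        amp = self.activity_level
        if sex == "F":
            amp *= self.sex_activity_mult
        if genotype == "MUT":
            amp *= self.genotype_activity_mult
        return amp


@dataclass
class GroundTruth:
    """Per-cage realized and target quantities for recovery tests."""

    cage_id: str
    target_rest_fraction: dict[str, float]
    realized_rest_fraction: dict[str, float]
    dwell_means: dict[str, tuple[float, float]]
    amplitude: float


def expected_rest_fraction(params: SimulationParams, genotype: str) -> dict[str, float]:
    """Renewal-theory stationary rest fraction per phase.

    With alternating rest/active dwells of means m_r and m_a the long-run
    rest fraction is m_r / (m_r + m_a); dwell means are short relative to
    an hour, so the hourly circadian modulation enters by averaging the
    hour-wise fraction over each phase's hours.  Day-to-day log-normal
    variation of the rest dwell is integrated out by Gauss-Hermite
    quadrature on the log scale.
    """
    means = params.dwell_means(genotype)
    s = params.day_effect_sigma
    nodes, weights = np.polynomial.hermite_e.hermegauss(21)
    fac = np.exp(nodes * s - s**2 / 2)  # E[factor] = 1
    w = weights / weights.sum()
    out = {}
    for phase, hours in ((LIGHT, range(12)), (DARK, range(12, 24))):
        m_r, m_a = means[phase]
        fr = [
            float(np.sum(w * (m_r * fac) / (m_r * fac + m_a * params.circadian_profile[h])))
            for h in hours
        ]
        out[phase] = float(np.mean(fr))
    return out


def _hour_of_second(sec_into_recording: int) -> int:
    """Hour post lights-on (0..23); the recording starts at lights-on."""
    return (sec_into_recording % SECONDS_PER_DAY) // 3600


def simulate_cage(
    params: SimulationParams, meta: CageMetadata, seed: int
) -> tuple[ImmobilitySeries, ActivitySeries, GroundTruth]:
    """Simulate one cage for the full recording span.

    The recording starts at lights-on on ``params.start_date`` and runs
    ``weeks`` whole weeks.  Deterministic per (params, meta, seed).
    """
    rng = np.random.default_rng(seed)
    total_s = params.weeks * 7 * SECONDS_PER_DAY
    means = params.dwell_means(meta.genotype)
    sigma = params.dwell_sigma
    profile = np.asarray(params.circadian_profile)

    # per-day, per-phase biological variation of the rest dwell mean
    n_days = params.weeks * 7
    s_day = params.day_effect_sigma
    day_rest_mult = rng.lognormal(-s_day**2 / 2, s_day, (n_days, 2))

    # alternate REST / ACTIVE; dwell drawn at state onset from a log-normal
    # whose mean reflects the phase, the hour's multiplier (ACTIVE) and the
    # day's rest-propensity factor (REST)
    states = []  # (state, duration)
    pos = 0
    state = 0 if rng.random() < 0.5 else 1  # 1 = REST
    while pos < total_s:
        hour = _hour_of_second(pos)
        day = pos // SECONDS_PER_DAY
        phase = LIGHT if hour < 12 else DARK
        m_r, m_a = means[phase]
        m_r = m_r * day_rest_mult[day, 0 if phase == LIGHT else 1]
        mean = m_r if state == 1 else m_a * profile[hour]
        mu = np.log(mean) - sigma**2 / 2
        dur = max(1, int(round(rng.lognormal(mu, sigma))))
        dur = min(dur, total_s - pos)
        states.append((state, dur))
        pos += dur
        state = 1 - state

    state_arr = np.repeat(
        np.array([s for s, _ in states], dtype=np.int8),
        np.array([d for _, d in states]),
    )
    immobile = (state_arr == 1).astype(np.int8)

    start_time = pd.Timestamp(
        dt.datetime.combine(params.start_date, params.schedule.lights_on)
    )
    imm = ImmobilitySeries(cage_id=meta.cage_id, start_time=start_time, values=immobile)

    # minute activity: ACTIVE fraction of the minute x amplitude + noise
    n_min = total_s // 60
    active_frac = (1 - immobile).reshape(n_min, 60).mean(axis=1)
    amp = params.amplitude(meta.sex, meta.genotype)
    noise = rng.normal(0.0, params.activity_noise_sd, n_min)
    activity = np.clip(active_frac * amp + noise * (active_frac > 0), 0.0, 1.0)
    act = ActivitySeries(cage_id=meta.cage_id, start_time=start_time, values=activity)

    sec_hours = (np.arange(total_s) % SECONDS_PER_DAY) // 3600
    is_light = sec_hours < 12
    realized = {
        LIGHT: float(immobile[is_light].mean()),
        DARK: float(immobile[~is_light].mean()),
    }
    truth = GroundTruth(
        cage_id=meta.cage_id,
        target_rest_fraction=expected_rest_fraction(params, meta.genotype),
        realized_rest_fraction=realized,
        dwell_means=means,
        amplitude=amp,
    )
    return imm, act, truth


def emit_capacitance(
    imm: ImmobilitySeries,
    params: SimulationParams,
    seed: int,
    fs: float = 4.0,
) -> CapacitanceRecord:
    """Optional raw-signal emission for exercising the activation stage.

    Immobile seconds carry sub-threshold Gaussian jitter on all electrodes;
    each active second puts supra-threshold jumps on 1–3 random electrodes.
    """
    rng = np.random.default_rng(seed)
    per_sec = int(round(fs))
    # one extra leading second: the activation stage drops the first second
    n = (len(imm.values) + 1) * per_sec
    values = rng.normal(0.0, params.capacitance_noise_sd, (n, N_ELECTRODES))
    active_secs = np.flatnonzero(imm.values == 0)
    for s in active_secs:
        k = int(rng.integers(1, 4))
        electrodes = rng.choice(N_ELECTRODES, size=k, replace=False)
        sample = (s + 1) * per_sec + int(rng.integers(0, per_sec))
        values[sample, electrodes] += params.capacitance_jump * rng.choice([-1, 1], k)
    return CapacitanceRecord(
        cage_id=imm.cage_id,
        start_time=imm.start_time - pd.Timedelta(seconds=1),
        fs=fs,
        values=values,
    )


@dataclass
class Cohort:
    """In-memory simulated dataset plus its ground truth."""

    params: SimulationParams
    metadata: list[CageMetadata]
    immobility: dict[str, ImmobilitySeries]
    activity: dict[str, ActivitySeries]
    truth: dict[str, GroundTruth]


def cage_change_dates(params: SimulationParams) -> frozenset[dt.date]:
    """Weekly cage-change dates on the configured weekday."""
    dates = []
    d = params.start_date
    # first occurrence of the weekday on/after start
    d += dt.timedelta(days=(params.cage_change_weekday - d.weekday()) % 7)
    end = params.start_date + dt.timedelta(days=7 * params.weeks)
    while d < end:
        dates.append(d)
        d += dt.timedelta(days=7)
    return frozenset(dates)


def simulate_cohort(params: SimulationParams) -> Cohort:
    """Simulate the full factorial cohort (all four sex×genotype groups).

    Cage seeds are spawned from ``params.seed`` so each cage is independent
    and the whole cohort is reproducible from the one top-level seed.
    """
    changes = cage_change_dates(params)
    metadata = []
    idx = 1
    for (sex, gen) in sorted(params.n_cages):
        for _ in range(params.n_cages[(sex, gen)]):
            metadata.append(
                CageMetadata(
                    cage_id=f"C{idx:02d}",
                    genotype=gen,
                    sex=sex,
                    cohort_id="SIM",
                    cage_change_dates=changes,
                )
            )
            idx += 1
    ss = np.random.SeedSequence(params.seed)
    children = ss.spawn(len(metadata))
    immobility, activity, truth = {}, {}, {}
    for meta, child in zip(metadata, children):
        seed = int(child.generate_state(1)[0] % (2**31))
        imm, act, gt = simulate_cage(params, meta, seed)
        immobility[meta.cage_id] = imm
        activity[meta.cage_id] = act
        truth[meta.cage_id] = gt
    return Cohort(
        params=params,
        metadata=metadata,
        immobility=immobility,
        activity=activity,
        truth=truth,
    )


def null_params(params: SimulationParams | None = None, **overrides) -> SimulationParams:
    """A copy of ``params`` with all group effects switched off."""
    base = params or SimulationParams()
    return replace(
        base,
        genotype_rest_dark_mult=1.0,
        genotype_activity_mult=1.0,
        sex_activity_mult=1.0,
        **overrides,
    )
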