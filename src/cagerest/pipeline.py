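"""End-to-end orchestration: series → per-day metrics → weekly tables → stats.

The stage order mirrors the analysis workflow: activation-derived series
(or simulated ones) feed the per-cage metrics (activity means, RDI,
percent-zero, least active hour, rest bouts); cage-change days are
excluded; days are averaged into weeks; and the weekly cage×week tables go
to the rank-based tests.  Every output row is traceable to its inputs via
the logged configuration hash, and a rerun with identical inputs and
configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import rest as rest_mod
from .datamodel import (
    DARK,
    LIGHT,
    ActivitySeries,
    AnalysisConfig,
    CageMetadata,
    ImmobilitySeries,
    LightSchedule,
)
from .phases import assign_phases, exclude_days, weekly_aggregate
from .rdi import compute_rdi
from .stats import (
    ats_f2_ld_f1,
    ats_to_frame,
    bonferroni,
    wilcoxon_two_sample,
)
from .synthetic import Cohort

logger = logging.getLogger(__name__)

PHASE_METRICS = ("activity_mean", "rdi", "pct_zero")

_CSV_FLOAT_FMT = "%.10g"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def config_hash(cfg: AnalysisConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def daily_phase_metrics(
    act: ActivitySeries,
    imm: ImmobilitySeries,
    schedule: LightSchedule,
    cfg: AnalysisConfig,
) -> pd.DataFrame:
    """Tidy per-day per-phase metric rows for one cage.

    Metrics: ``activity_mean`` (mean minute activity), ``rdi``, and
    ``pct_zero`` (percent of unmasked seconds immobile).  Only complete
    720-minute phases are scored.
    """
    rows = []
    labels = assign_phases(act.timestamps(), schedule)
    adf = labels.assign(value=act.values)
    expected_min = int(schedule.phase_length_hours * 60)
    for (day, phase), g in adf.groupby(["day", "phase"], sort=True):
        if len(g) != expected_min:
            continue
        rows.append(
            {
                "cage_id": act.cage_id,
                "day": day,
                "phase": phase,
                "metric": "activity_mean",
                "value": float(np.nanmean(g["value"].to_numpy())),
            }
        )
    rdi_df = compute_rdi(act, schedule, cfg)
    for r in rdi_df.itertuples():
        rows.append(
            {
                "cage_id": r.cage_id,
                "day": r.day,
                "phase": r.phase,
                "metric": "rdi",
                "value": r.rdi,
            }
        )
    counts = rest_mod._hourly_counts(imm, schedule)
    expected_s = expected_min * 60
    byphase = (
        counts.groupby(["day", "phase"], sort=True)[["immobile_s", "ok_s", "n_s"]]
        .sum()
        .reset_index()
    )
    for r in byphase.itertuples():
        if r.n_s != expected_s or r.ok_s == 0:
            continue
        rows.append(
            {
                "cage_id": imm.cage_id,
                "day": r.day,
                "phase": r.phase,
                "metric": "pct_zero",
                "value": 100.0 * r.immobile_s / r.ok_s,
            }
        )
    return pd.DataFrame(rows, columns=["cage_id", "day", "phase", "metric", "value"])


def cohort_metrics(cohort: Cohort, cfg: AnalysisConfig) -> dict[str, pd.DataFrame]:
    """All metric tables for a simulated cohort, cage-change days excluded."""
    schedule = cohort.params.schedule
    meta = {m.cage_id: m for m in cohort.metadata}
    daily, hourly, lah, bouts = [], [], [], []
    for cage_id in sorted(meta):
        act = cohort.activity[cage_id]
        imm = cohort.immobility[cage_id]
        daily.append(daily_phase_metrics(act, imm, schedule, cfg))
        hourly.append(rest_mod.percent_zero_per_hour(imm, schedule))
        lah.append(rest_mod.least_active_hour(act, schedule))
        bouts.append(
            rest_mod.detect_rest_bouts(
                imm,
                schedule,
                bout_min=cfg.bout_min,
                split_at_phase_boundary=cfg.split_bouts_at_phase_boundary,
            )
        )
    tables = {
        "daily": pd.concat(daily, ignore_index=True),
        "hourly_pct_zero": pd.concat(hourly, ignore_index=True),
        "least_active_hour": pd.concat(lah, ignore_index=True),
        "bouts": pd.concat(bouts, ignore_index=True),
    }
    tables["daily"] = exclude_days(tables["daily"], meta)
    tables["hourly_pct_zero"] = exclude_days(tables["hourly_pct_zero"], meta)
    tables["least_active_hour"] = exclude_days(tables["least_active_hour"], meta)
    tables["bouts"] = exclude_days(tables["bouts"], meta)

    tables["weekly"] = weekly_aggregate(
        tables["daily"], start_day=cohort.params.start_date
    )

    # per-cage per-phase bout summaries over the whole included recording
    rows = []
    for cage_id, g in tables["bouts"].groupby("cage_id", sort=True):
        for phase in (LIGHT, DARK):
            hist = rest_mod.time_weighted_histogram(g, phase, cfg.bout_bins)
            for h in hist.itertuples():
                rows.append(
                    {
                        "cage_id": cage_id,
                        "phase": phase,
                        "metric": f"bout_weight[{h.bin}]",
                        "value": h.weight,
                    }
                )
            rows.append(
                {
                    "cage_id": cage_id,
                    "phase": phase,
                    "metric": f"long_bout_fraction[>{cfg.long_bout_threshold:g}min]",
                    "value": rest_mod.long_bout_fraction(
                        g, phase, cfg.long_bout_threshold
                    ),
                }
            )
    tables["bout_summary"] = pd.DataFrame(
        rows, columns=["cage_id", "phase", "metric", "value"]
    )
    return tables


def attach_design(table: pd.DataFrame, metadata: list[CageMetadata]) -> pd.DataFrame:
    info = pd.DataFrame(
        [{"cage_id": m.cage_id, "sex": m.sex, "genotype": m.genotype} for m in metadata]
    )
    return table.merge(info, on="cage_id", how="left")


def run_stats(
    weekly: pd.DataFrame,
    bout_summary: pd.DataFrame,
    metadata: list[CageMetadata],
) -> pd.DataFrame:
    """ATS for each weekly phase metric + Bonferroni Wilcoxon post-hocs.

    The ANOVA-type tests run on cage×week tables per (metric, phase).
    Post-hoc two-sample Wilcoxon tests compare genotypes within each sex on
    per-cage bout-bin weights, Bonferroni-corrected over the bins of each
    (phase, sex) family.
    """
    rows = []
    w = attach_design(weekly, metadata)
    for (metric, phase), g in w.groupby(["metric", "phase"], sort=True):
        design = g.rename(columns={"value": "value"})[
            ["cage_id", "sex", "genotype", "week", "value"]
        ].dropna(subset=["value"])
        try:
            results = ats_f2_ld_f1(design)
        except Exception as exc:  # incomplete design (e.g. tiny cohorts)
            logger.warning("ATS skipped for %s/%s: %s", metric, phase, exc)
            continue
        for r in ats_to_frame(results).itertuples():
            rows.append(
                {
                    "metric": metric,
                    "phase": phase,
                    "test": "ats",
                    "effect": r.effect,
                    "statistic": r.statistic,
                    "df": r.df,
                    "p": r.p,
                    "p_adj": np.nan,
                }
            )

    b = attach_design(bout_summary, metadata)
    for phase, gphase in b.groupby("phase", sort=True):
        for sex, gsex in gphase.groupby("sex", sort=True):
            fam = []
            for metric, gm in gsex.groupby("metric", sort=True):
                x = gm.loc[gm["genotype"] == "MUT", "value"].to_numpy()
                y = gm.loc[gm["genotype"] == "WT", "value"].to_numpy()
                if x.size == 0 or y.size == 0:
                    continue
                stat, p = wilcoxon_two_sample(x, y)
                fam.append((metric, stat, p))
            if not fam:
                continue
            p_adj = bonferroni([p for _, _, p in fam], m=len(fam))
            for (metric, stat, p), pa in zip(fam, p_adj):
                rows.append(
                    {
                        "metric": metric,
                        "phase": phase,
                        "test": f"wilcoxon[{sex}:MUTvsWT]",
                        "effect": "Genotype",
                        "statistic": stat,
                        "df": np.nan,
                        "p": p,
                        "p_adj": pa,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["metric", "phase", "test", "effect", "statistic", "df", "p", "p_adj"],
    )


def group_phase_means(
    tables: dict[str, pd.DataFrame], metadata: list[CageMetadata]
) -> pd.DataFrame:
    """Group (sex×genotype) mean of each phase metric — the headline summary."""
    daily = attach_design(tables["daily"], metadata)
    per_cage = (
        daily.groupby(["cage_id", "sex", "genotype", "phase", "metric"], sort=True)[
            "value"
        ]
        .mean()
        .reset_index()
    )
    bout = attach_design(tables["bout_summary"], metadata)
    per_cage = pd.concat(
        [per_cage, bout[["cage_id", "sex", "genotype", "phase", "metric", "value"]]],
        ignore_index=True,
    )
    return (
        per_cage.groupby(["sex", "genotype", "phase", "metric"], sort=True)["value"]
        .mean()
        .reset_index()
    )


def run_pipeline(
    cohort: Cohort,
    cfg: AnalysisConfig,
    out_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Run every stage on a cohort; optionally write the CSV bundle."""
    stage = "metrics"
    try:
        tables = cohort_metrics(cohort, cfg)
        stage = "stats"
        tables["stats"] = run_stats(
            tables["weekly"], tables["bout_summary"], cohort.metadata
        )
        stage = "summary"
        tables["group_summary"] = group_phase_means(tables, cohort.metadata)
        lah = attach_design(tables["least_active_hour"], cohort.metadata)
        rows = []
        for (sex, gen), g in lah.groupby(["sex", "genotype"], sort=True):
            _, dark_frac = rest_mod.least_active_hour_histogram(g)
            rows.append(
                {"sex": sex, "genotype": gen, "dark_fraction": dark_frac, "n": len(g)}
            )
        tables["lah_dark_fraction"] = pd.DataFrame(rows)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        logger.info("config hash %s", config_hash(cfg))
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False, float_format=_CSV_FLOAT_FMT)
    return tables
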