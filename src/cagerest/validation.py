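"""Self-validation utilities: test calibration, parameter recovery, and
qualitative reproduction of the mutant rest phenotype on synthetic cohorts.

These functions exist so that the package can demonstrate, from scratch and
under its own generative model, that (a) the rank-based tests hold their
nominal level, (b) the simulator realises the rest fractions it promises,
and (c) the full analysis pipeline recovers the direction of every headline
group contrast when the generative mutant effects are switched on:
mutants less active and less fragmented (lower RDI) in the dark, resting
more (higher percent-zero), with heavier long-bout tails and more dark
least-active hours.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .datamodel import DARK, AnalysisConfig
from .pipeline import attach_design, cohort_metrics
from .rest import least_active_hour_histogram
from .stats import ats_f2_ld_f1, wilcoxon_two_sample
from .synthetic import DEFAULT_N_CAGES, SimulationParams, simulate_cohort

#: (metric, expected sign of MUT − WT) for the dark-phase headline contrasts
HEADLINE_CONTRASTS = (
    ("activity_mean", -1),
    ("rdi", -1),
    ("pct_zero", +1),
    ("bout_weight_gt15", +1),
    ("long_bout_fraction", +1),
    ("lah_dark_fraction", +1),
)


def null_weekly_table(
    rng: np.random.Generator,
    sizes: dict[tuple[str, str], int] | None = None,
    weeks: int = 5,
) -> pd.DataFrame:
    """A cage×week metric table with no group effect.

    Cages are exchangeable across sex/genotype labels: each cage gets a
    random subject effect plus independent weekly noise, so any test of a
    group factor sees its null.
    """
    sizes = dict(DEFAULT_N_CAGES) if sizes is None else sizes
    rows = []
    cid = 0
    for (sex, gen), n in sizes.items():
        for _ in range(n):
            cid += 1
            subj = rng.normal(0.0, 1.0)
            vals = subj + rng.normal(0.0, 1.0, weeks)
            for w in range(weeks):
                rows.append(
                    {
                        "cage_id": f"C{cid:02d}",
                        "sex": sex,
                        "genotype": gen,
                        "week": w + 1,
                        "value": vals[w],
                    }
                )
    return pd.DataFrame(rows)


def ats_genotype_type_one_error(
    n_sim: int = 1000, seed: int = 0, alpha: float = 0.05
) -> float:
    """Rejection rate of the genotype ANOVA-type test under the null."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sim):
        table = null_weekly_table(rng)
        res = ats_f2_ld_f1(table, effects=("Genotype",))[0]
        if res.p is not None and res.p < alpha:
            hits += 1
    return hits / n_sim


def wilcoxon_type_one_error(
    n_sim: int = 1000, seed: int = 0, n_x: int = 10, n_y: int = 10,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of the exact two-sample Wilcoxon test under the null."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sim):
        x = rng.normal(size=n_x)
        y = rng.normal(size=n_y)
        _, p = wilcoxon_two_sample(x, y, mode="exact")
        if p < alpha:
            hits += 1
    return hits / n_sim


def group_recovery_errors(params: SimulationParams) -> pd.DataFrame:
    """Group-mean realized minus target rest fraction, per genotype and phase."""
    cohort = simulate_cohort(params)
    rows = []
    by_geno: dict[tuple[str, str], list[float]] = {}
    for meta in cohort.metadata:
        truth = cohort.truth[meta.cage_id]
        for phase in ("LIGHT", "DARK"):
            by_geno.setdefault((meta.genotype, phase), []).append(
                truth.realized_rest_fraction[phase] - truth.target_rest_fraction[phase]
            )
    for (genotype, phase), errs in sorted(by_geno.items()):
        rows.append(
            {
                "genotype": genotype,
                "phase": phase,
                "mean_error": float(np.mean(errs)),
                "max_abs_error": float(np.max(np.abs(errs))),
                "n_cages": len(errs),
            }
        )
    return pd.DataFrame(rows)


def dark_contrasts(cohort, cfg: AnalysisConfig) -> dict[str, float]:
    """MUT − WT group differences for every dark-phase headline metric."""
    tables = cohort_metrics(cohort, cfg)
    daily = attach_design(tables["daily"], cohort.metadata)
    dark = daily[daily["phase"] == DARK]
    per_cage = (
        dark.groupby(["cage_id", "genotype", "metric"], sort=True)["value"]
        .mean()
        .reset_index()
    )
    group = per_cage.groupby(["genotype", "metric"], sort=True)["value"].mean()

    out = {}
    for metric in ("activity_mean", "rdi", "pct_zero"):
        out[metric] = float(group[("MUT", metric)] - group[("WT", metric)])

    bout = attach_design(tables["bout_summary"], cohort.metadata)
    bdark = bout[bout["phase"] == DARK]
    for key, prefix in (
        ("bout_weight_gt15", "bout_weight[>15"),
        ("long_bout_fraction", "long_bout_fraction"),
    ):
        sel = bdark[bdark["metric"].str.startswith(prefix)]
        g = sel.groupby("genotype")["value"].mean()
        out[key] = float(g["MUT"] - g["WT"])

    lah = attach_design(tables["least_active_hour"], cohort.metadata)
    fracs = {}
    for genotype, g in lah.groupby("genotype"):
        _, fracs[genotype] = least_active_hour_histogram(g)
    out["lah_dark_fraction"] = float(fracs["MUT"] - fracs["WT"])
    return out


def full_pattern(contrasts: dict[str, float]) -> bool:
    """True when every headline contrast has the mutant-phenotype sign."""
    return all(sign * contrasts[m] > 0 for m, sign in HEADLINE_CONTRASTS)


def direction_consistency(
    n_cohorts: int = 100,
    seed: int = 0,
    cages_per_group: int = 4,
    weeks: int = 1,
    cfg: AnalysisConfig | None = None,
) -> tuple[int, list[dict[str, float]]]:
    """Count replicate cohorts reproducing the full mutant direction pattern.

    Cohorts are scaled down from the study layout (fewer cages, shorter
    span) purely for throughput; the generative group effects are the
    defaults.  Returns (count, per-cohort contrast dicts).
    """
    cfg = cfg or AnalysisConfig()
    sizes = {k: cages_per_group for k in DEFAULT_N_CAGES}
    hits = 0
    all_contrasts = []
    for i in range(n_cohorts):
        params = SimulationParams(n_cages=sizes, weeks=weeks, seed=seed + i)
        cohort = simulate_cohort(params)
        contrasts = dark_contrasts(cohort, cfg)
        all_contrasts.append(contrasts)
        if full_pattern(contrasts):
            hits += 1
    return hits, all_contrasts
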