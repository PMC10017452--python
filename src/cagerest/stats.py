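"""Rank-based inference for the longitudinal factorial design.

The study design is F2-LD-F1 in the nonparametric-longitudinal-data
taxonomy: two whole-plot (between-subject) factors — Sex and Genotype —
and one sub-plot (within-subject, repeated) factor — Week.  The subject is
the cage.  The test is the ANOVA-type statistic (ATS): a quadratic form in
the cell relative treatment effects, computed from mid-ranks over the
pooled sample, referred to an F(f̂, ∞) distribution with Box-approximated
numerator degrees of freedom.  Rank-based, it is invariant under strictly
monotone transforms of the metric and needs no distributional assumptions
beyond exchangeability under the null.

Relative treatment effect of cell c: p̂_c = (mean mid-rank in c − 1/2)/N,
the probability that a random observation from the pooled distribution is
smaller than one from cell c (ties split).  Effects lie in (0, 1) and equal
1/2 everywhere when all groups share one distribution.

Post-hoc pairwise comparisons use two-sample Wilcoxon (rank-sum) tests with
Bonferroni correction over the comparison family.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

SEX_LEVELS = ("M", "F")
GENOTYPE_LEVELS = ("WT", "MUT")

EFFECTS = (
    "Sex",
    "Genotype",
    "Week",
    "Sex:Genotype",
    "Sex:Week",
    "Genotype:Week",
    "Sex:Genotype:Week",
)


class DesignError(ValueError):
    """The design table violates the F2-LD-F1 layout."""


@dataclass(frozen=True)
class AtsResult:
    effect: str
    statistic: float
    df: float
    p: float | None
    degenerate: bool = False


def _layout(table: pd.DataFrame):
    """Validate and pivot a tidy cage×week table to per-cell subject matrices.

    ``table`` columns: cage_id, sex, genotype, week, value.  Every cage must
    sit in exactly one (sex, genotype) cell and have a value for every week.
    Returns (weeks, dict[(sex, genotype)] -> (n_ij, t) array).
    """
    required = {"cage_id", "sex", "genotype", "week", "value"}
    missing = required - set(table.columns)
    if missing:
        raise DesignError(f"design table missing columns: {sorted(missing)}")
    weeks = np.sort(table["week"].unique())
    cells = {}
    seen_cages = set()
    for (sex, gen), g in table.groupby(["sex", "genotype"], sort=True):
        wide = g.pivot_table(
            index="cage_id", columns="week", values="value", aggfunc="first"
        ).reindex(columns=weeks)
        if wide.isna().any().any():
            bad = wide.index[wide.isna().any(axis=1)].tolist()
            raise DesignError(
                f"cages {bad} in cell ({sex},{gen}) lack a value for some week"
            )
        if len(wide) < 2:
            raise DesignError(f"cell ({sex},{gen}) needs >= 2 cages")
        overlap = seen_cages & set(wide.index)
        if overlap:
            raise DesignError(f"cages {sorted(overlap)} appear in more than one cell")
        seen_cages |= set(wide.index)
        cells[(sex, gen)] = wide.to_numpy(dtype=float)
    return weeks, cells


def relative_effects(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell relative treatment effects p̂ = (mean mid-rank − 1/2)/N."""
    weeks, cells = _layout(table)
    keys = sorted(cells)
    stacked = np.concatenate([cells[k].ravel() for k in keys])
    n_total = stacked.size
    ranks = sps.rankdata(stacked)  # mid-ranks
    rows = []
    pos = 0
    for k in keys:
        arr = cells[k]
        r = ranks[pos : pos + arr.size].reshape(arr.shape)
        pos += arr.size
        for j, w in enumerate(weeks):
            rows.append(
                {
                    "sex": k[0],
                    "genotype": k[1],
                    "week": w,
                    "p_hat": (r[:, j].mean() - 0.5) / n_total,
                    "n_cages": arr.shape[0],
                }
            )
    return pd.DataFrame(rows)


def _projection(effect: str, t: int) -> np.ndarray:
    """Projection matrix onto the contrast space of an effect.

    Cell-mean vector ordering: sex (a=2) slowest, genotype (b=2), week (t)
    fastest.  Factors present in the effect get the centring matrix
    P = I − J/n, absent factors the averaging matrix J/n; the Kronecker
    product of projections is a projection.
    """
    parts = set(effect.split(":"))
    unknown = parts - {"Sex", "Genotype", "Week"}
    if unknown:
        raise ValueError(f"unknown factors in effect {effect!r}")

    def mat(name: str, n: int) -> np.ndarray:
        if name in parts:
            return np.eye(n) - np.full((n, n), 1.0 / n)
        return np.full((n, n), 1.0 / n)

    out = np.kron(np.kron(mat("Sex", 2), mat("Genotype", 2)), mat("Week", t))
    return out


def ats_f2_ld_f1(
    table: pd.DataFrame, effects: tuple[str, ...] = EFFECTS
) -> list[AtsResult]:
    """ANOVA-type statistics for the Sex×Genotype×Week design.

    For each requested effect with projection T:
        F = N · p̂ᵀ T p̂ / tr(T V̂),    f̂ = tr(T V̂)² / tr(T V̂ T V̂),
    where p̂ is the (2·2·t)-vector of cell relative effects and V̂ the
    block-diagonal estimate N·⊕ S_ij/n_ij built from the subjects'
    normalised rank vectors.  p-values refer F to F(f̂, ∞), i.e. χ²_f̂/f̂.
    A design with zero rank variance is degenerate: statistic NaN, no p.
    """
    weeks, cells = _layout(table)
    t = len(weeks)
    keys = list(
        itertools.product(SEX_LEVELS, GENOTYPE_LEVELS)
    )  # fixed order: sex slowest
    present = sorted(cells)
    if set(present) != set(keys):
        raise DesignError(
            f"expected the four cells {keys}, got {present}"
        )
    stacked = np.concatenate([cells[k].ravel() for k in keys])
    n_total = stacked.size
    ranks = sps.rankdata(stacked)

    p_hat = np.empty(4 * t)
    v_blocks = []
    pos = 0
    for ci, k in enumerate(keys):
        arr = cells[k]
        n_ij = arr.shape[0]
        r = ranks[pos : pos + arr.size].reshape(arr.shape) / n_total
        pos += arr.size
        p_hat[ci * t : (ci + 1) * t] = r.mean(axis=0) - 0.5 / n_total
        s_ij = np.cov(r, rowvar=False, ddof=1).reshape(t, t)
        v_blocks.append(s_ij / n_ij)
    n_subjects = sum(cells[k].shape[0] for k in keys)
    v_hat = n_subjects * _block_diag(v_blocks)

    results = []
    for effect in effects:
        t_mat = _projection(effect, t)
        tv = t_mat @ v_hat
        denom = float(np.trace(tv))
        quad = float(p_hat @ t_mat @ p_hat)
        if denom <= 1e-14:
            results.append(AtsResult(effect, np.nan, np.nan, None, degenerate=True))
            continue
        stat = n_subjects * quad / denom
        df = denom**2 / float(np.trace(tv @ tv))
        p = float(sps.chi2.sf(stat * df, df))
        results.append(AtsResult(effect, stat, df, p))
    return results


def _block_diag(blocks: list[np.ndarray]) -> np.ndarray:
    sizes = [b.shape[0] for b in blocks]
    out = np.zeros((sum(sizes), sum(sizes)))
    pos = 0
    for b in blocks:
        k = b.shape[0]
        out[pos : pos + k, pos : pos + k] = b
        pos += k
    return out


def ats_to_frame(results: list[AtsResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "effect": r.effect,
                "statistic": r.statistic,
                "df": r.df,
                "p": np.nan if r.p is None else r.p,
                "degenerate": r.degenerate,
            }
            for r in results
        ]
    )


def wilcoxon_two_sample(
    x: np.ndarray, y: np.ndarray, mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided two-sample Wilcoxon (Mann-Whitney) test.

    ``mode='exact'`` enumerates the permutation null (valid without ties);
    ``'normal'`` uses the mid-rank normal approximation with tie correction;
    ``'auto'`` picks exact when n_x + n_y <= 20 and the data are tie-free.
    Returns (U statistic of x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if (x.size + y.size <= 20 and not has_ties) else "normal"
    if mode == "exact" and has_ties:
        mode = "normal"  # the exact null distribution assumes no ties
    method = "exact" if mode == "exact" else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bonferroni(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m·p), order preserved."""
    p = np.asarray(pvals, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("family size m must be >= number of p-values")
    return np.minimum(1.0, m * p)
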