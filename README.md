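# cagerest

Home-cage monitoring analytics for rest/activity phenotyping of group-housed
mice, built for capacitance-sensor ("digital ventilated cage") recordings.

Frail disease models — here motivated by a transgenic model of myotonic
dystrophy type 1, which shows an excessive-rest phenotype echoing the
excessive daytime sleepiness of patients — often cannot tolerate EEG
implantation. Continuous, unobtrusive home-cage monitoring provides
behaviourally defined sleep proxies instead. `cagerest` implements that
analysis chain as a tested, reusable library:

- **activation** — electrode activation density: per-minute activity index
  in [0, 1] from thresholded consecutive capacitance differences, and
  per-second binary immobility (λ = 1.25 on consecutive 1-s averages;
  1 = both cage mates immobile).
- **rdi** — Regularity Disruption Index: sample entropy
  SampEn(m=2, r=0.2·SD) of the zero-phase Butterworth band-pass-filtered
  minute-activity series per 12-h light/dark phase. RDI ≈ 0 for
  consolidated (rest-like) phases, high for fragmented activity.
- **rest** — percent zero-activity per hour post lights-on, the least
  active consecutive hour of each day, rest bouts (maximal immobility runs
  ≥ 40 s, the standard mouse sleep proxy), time-weighted duration
  histograms (<5, 5–15, >15 min) and the >30-min long-bout fraction.
- **stats** — rank-based ANOVA-type statistics for the longitudinal
  factorial design (Sex × Genotype whole-plot, Week sub-plot, cage as the
  experimental unit) with Box-approximated degrees of freedom, plus
  Bonferroni-corrected two-sample Wilcoxon post-hocs.
- **synthetic** — a two-state (REST/ACTIVE) circadian semi-Markov cohort
  generator with per-group effect sizes and exported ground truth, used
  for parameter-recovery, calibration and power checks.

See `docs/methods.md` for the model details, conventions (lights-on-anchored
days, half-open phases, mask propagation) and known limitations.

## Worked example

Simulate a small cohort and run the full pipeline (activity → RDI/rest
metrics → weekly aggregation → statistics):

```sh
cagerest all --seed 11 --weeks 1 --cages-per-group 2 --out-dir results/demo --no-figures
```

which writes `daily.csv`, `weekly.csv`, `bouts.csv`, `bout_summary.csv`,
`stats.csv`, `group_summary.csv`, … into `results/demo/`. The dark-phase
group summary of that run:

```
sex genotype phase        metric     value
  F      MUT  DARK activity_mean  0.109754
  F      MUT  DARK      pct_zero 49.954282
  F      MUT  DARK           rdi  0.979325
  F       WT  DARK activity_mean  0.193945
  F       WT  DARK      pct_zero 38.064236
  F       WT  DARK           rdi  1.237374
```

Mutant cages are less active in the dark phase, their activity pattern is
less fragmented (lower RDI — more consolidated rest), and they spend a
larger share of dark-phase seconds with both animals immobile: the
excessive-rest-during-the-active-phase phenotype, recovered by the
pipeline from simulated recordings. `stats.csv` carries the corresponding
ANOVA-type tests (`effect = Genotype`, …) and Bonferroni-adjusted Wilcoxon
post-hocs.

The same stages are available programmatically:

```python
from cagerest import AnalysisConfig, SimulationParams, run_pipeline, simulate_cohort

cohort = simulate_cohort(SimulationParams(weeks=5, seed=11))
tables = run_pipeline(cohort, AnalysisConfig())
print(tables["stats"].query("test == 'ats' and effect == 'Genotype'"))
```

To start from raw capacitance CSVs instead, use
`cagerest activity --in capacitance.csv --fs 4 ...` followed by
`cagerest rdi` / `cagerest rest`.

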