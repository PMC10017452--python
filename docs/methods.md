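# Methods

`cagerest` implements the analysis chain used in capacitance-based home-cage
monitoring of group-housed mice, with a focus on rest/sleep-proxy
phenotyping: raw electrode capacitance → activity and immobility series →
regularity and rest-bout metrics per light/dark phase → rank-based
longitudinal inference. A generative cohort simulator provides fully
specified synthetic data for validation, calibration and power analysis.

## Signal model

A cage sits on a board of 12 capacitance electrodes sampled at a fixed rate
(default 4 Hz, configurable — vendor hardware rates vary and only density
ratios depend on it). An electrode is *activated* in a comparison window
when the absolute difference of two consecutive capacitance measurements
exceeds a threshold λ chosen above the sensor noise floor. Two readouts are
derived:

- **Activity index (activation density).** Per minute: activated
  (electrode, consecutive-sample) pairs divided by all unmasked pairs
  (2880 at 4 Hz). Values lie in [0, 1]. An optional centred moving average
  (default 3 min) yields the smoothed index; the exact vendor smoothing
  kernel is not public, so the kernel here is a documented package choice
  and all downstream metrics accept raw or smoothed input.
- **Immobility.** Per second, using the lowest usable threshold
  λ = 1.25 applied to *consecutive 1-s average windows* per electrode: a
  second is immobile only if no electrode moved. Because two mice share the
  cage, immobility means *both* animals are still; the cage, not the
  animal, is the experimental unit everywhere.

Missing samples are masked, never zero-filled — fabricated zeros would be
indistinguishable from rest. Masks propagate: activation denominators count
only unmasked pairs, immobility runs are broken by masked seconds (a gap is
never bridged into a rest bout), and per-hour percentages renormalise by
unmasked seconds.

## Calendar conventions

Days are anchored at lights-on (07:00 by default, 12:12 cycle), so hour 0
post lights-on is the first light hour and hour 12 the first dark hour;
phase intervals are half-open, `[on, off)`. Anchoring at lights-on rather
than midnight keeps hourly summaries phase-aligned; whether a "day" for
weekly averaging should instead run midnight→midnight is genuinely open,
and the lights-on convention is flagged here as the package's choice.
Cage-change days are excluded before any aggregation. Week 1 is the first
seven recording days.

## Regularity Disruption Index (RDI)

RDI for one 12-h phase segment of minute activity is the sample entropy of
the band-pass filtered segment:

- Zero-phase (forward–backward) Butterworth band-pass, order 2, passband
  periods 2.5–120 min. The passband keeps bout-scale structure while
  removing DC and circadian trend. The short-period edge cannot reach
  2 min: that is the Nyquist period at 1 sample/min, where a band-pass
  design degenerates, so 2.5 min is the closest usable default. Both edges
  and the order are configurable. Forward–backward filtering squares the
  one-pass magnitude response; tests check the gain against the closed-form
  Butterworth response at bilinear-prewarped frequencies.
- Sample entropy SampEn(m, r) = −ln(A/B), Richman–Moorman convention
  (N − m template positions for both lengths, self-matches excluded),
  m = 2 and r = 0.2 × SD of the *filtered* segment — the standard
  conventions; the originators of this metric do not publish their exact
  (m, r), so numerical equality with vendor RDI values is not claimed.
  Tolerance scaling by the segment SD makes the index invariant to affine
  rescaling and self-normalises LIGHT versus DARK.

Degenerate cases are deliberate: a (near-)constant filtered segment (SD
below 1e-12) returns RDI = 0 (perfect regularity); B = 0 returns missing
(`undefined`); A = 0 with B > 0 returns the capped value −ln(1/(B+1))
(`capped`) to avoid infinities in automated pipelines. Segments with more
than 20 % masked minutes are flagged `low_confidence`; interior gaps are
linearly interpolated before filtering so the filter sees a contiguous
series.

A consolidated phase (long uninterrupted rest) gives low RDI; minute-scale
alternation at matched total activity gives strictly higher RDI — the
property that makes RDI a rest-disruption proxy, and the property the tests
enforce.

## Rest metrics

- **Percent zero per hour**: share of unmasked seconds immobile, per hour
  post lights-on (0–23).
- **Least active hour**: the 60 consecutive minutes with minimal mean
  activity, scanning all 1381 starts within the lights-on-anchored day.
  Windows do not wrap across the day boundary; windows with more than 10
  masked minutes are skipped; ties break to the earliest start. Its
  occurrence in the dark (active) phase is the daytime-sleepiness-like
  signal.
- **Rest bouts**: maximal immobility runs of at least 40 s — the
  established behavioural sleep proxy for mice. A bout is attributed to the
  phase of its onset second (a bout straddling lights-off counts once); an
  alternative split-at-boundary mode is available behind a config flag and
  is what the per-phase conservation test uses, since onset attribution
  deliberately trades exact per-phase accounting for bout integrity.
- **Duration histograms**: time-weighted (each bout contributes its
  duration) and normalised by total phase rest, over bins [40 s, 5 min),
  [5, 15) and [15, ∞) minutes, plus the fraction of rest time in bouts
  longer than 30 min (strictly greater).

## Statistics

The design is longitudinal-factorial: Sex and Genotype as whole-plot
(between-cage) factors, Week as the sub-plot (within-cage) factor — the
F2-LD-F1 layout of the nonparametric longitudinal literature. Inference
uses the rank-based ANOVA-type statistic (ATS): mid-ranks over the pooled
sample give cell relative effects p̂ = (mean rank − ½)/N; for an effect
with projection matrix T built from Kronecker products of centring and
averaging matrices,

    F = n · p̂ᵀ T p̂ / tr(T V̂),   f̂ = tr(T V̂)² / tr(T V̂ T V̂),

with V̂ the block-diagonal covariance estimate from the subjects'
normalised rank vectors, referred to F(f̂, ∞) (equivalently χ²_f̂/f̂). For
two-level whole-plot effects T has rank one and f̂ = 1 exactly. The
statistic is invariant under strictly monotone transforms of the metric.
Known behaviour: with F(f̂, ∞) the whole-plot tests run slightly liberal in
small samples (measured ≈ 0.06 at nominal 0.05 with 39 cages); the
denominator-df ("modified Box") variant that would tighten this is not
implemented, and the degrees of freedom reported for sub-plot effects use
the Box approximation throughout. Zero rank variance yields a flagged
degenerate result instead of a p-value.

Post-hoc comparisons are two-sample Wilcoxon tests (exact enumeration when
n ≤ 20 without ties, mid-rank normal approximation with tie correction
otherwise — scipy's implementation behind the package's interface), with
Bonferroni correction over each comparison family (the bins of a
histogram panel, or the per-sex genotype contrasts of a metric).

## Synthetic cohorts

Each cage is a two-state (REST/ACTIVE) semi-Markov process at 1-s
resolution with log-normal dwell times (shape σ = 1) — the simplest
generative family with heavy-enough tails to span all duration bins.
Defaults encode the study conditions: four groups of 10/10/11/8 cages,
five weeks from lights-on on a Monday, weekly cage changes, 12:12 cycle.
Baseline dwell means (seconds): light 300 rest / 120 active, dark 110 rest /
260 active. A 24-value circadian profile multiplies the mean ACTIVE dwell
per hour; the default profile is rest-dominated in light, with crepuscular
activity peaks after lights-off and before lights-on and a mid-dark nap
dip (hours 16–19 post lights-on). The dip plus a per-day, per-phase
log-normal rest-dwell factor (σ = 0.3, mean 1) are what let the least
active hour occasionally fall in the dark — calibrated so that control
cages place ~3 % and mutant cages ~10–20 % of least-active hours in the
dark, the regime reported for this phenotype. Group effects are
multiplicative: mutants double the dark rest-dwell mean and scale activity
amplitude by 0.7; control females scale activity amplitude by 1.25.
Minute activity is the ACTIVE fraction of the minute times the group
amplitude plus clipped Gaussian noise. Optional capacitance emission
(sub-threshold jitter on immobile seconds, supra-threshold jumps on 1–3
electrodes on active seconds) exercises the activation stage end-to-end.

Ground truth accompanies every cage: the stationary rest-fraction target
per phase is m_r/(m_r + m_a·c(h)) averaged over the phase's hours, with
the day-level dwell factor integrated out by Gauss–Hermite quadrature.
Realised group-mean rest fractions recover these targets within ±0.03 over
five weeks (per-cage values vary more, dominated by the day-level factor).

What the generator does *not* emulate: per-animal behaviour within the
cage, position on the electrode grid, sensor drift and humidity artefacts,
litter/cohort effects, and ageing trends across the five weeks. Passing
tests therefore demonstrate correctness and calibration of the analysis
chain under a plausible generative model — not biological validity of any
particular threshold on real recordings.

## Validation suite and problem sizes

The acceptance tests check: exact agreement of every counting metric with
independent brute-force oracles on 100 random instances each (sample
entropy to 1e-9 relative); conservation and monotonicity invariants;
type-I error of the genotype ATS and the exact Wilcoxon within 0.05 ± 0.02
over 1000 null cohorts at study group sizes (generated at the weekly-table
level, where the tests operate); recovery of rest-fraction targets; and
reproduction of the full mutant direction pattern — lower dark activity
and RDI, higher dark percent-zero, heavier >15-min and >30-min bout
weights, more dark least-active hours — in ≥95 of 100 replicate cohorts.
The replicate cohorts are scaled to 4 cages/group × 1 week for throughput;
effect sizes are the generator defaults. `scripts/acceptance.py` re-runs
the same battery from scratch (30 replicate cohorts) plus a full
study-scale cohort through the complete pipeline, and writes all computed
quantities as JSON.
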