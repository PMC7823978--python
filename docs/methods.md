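# Methods

This note records the modelling assumptions, parameter choices and numerical
decisions behind `leashwalk`. It makes no empirical claims beyond what the
test suite and `scripts/acceptance.py` compute.

## Problem setting

A shelter walking study pairs volunteer walkers with shelter dogs: each
walker walks several *different* dogs, and dogs are reused across walkers, so
walker and dog grouping factors are **crossed**, not nested. Each walk
yields:

- a 10 Hz leash-tension / leash-acceleration trace from an in-line meter
  (0–100 kgf range, 0.1 kgf resolution; the signed acceleration axis points
  from handler toward dog);
- an ethogram event stream coded from video (state events with onset/offset,
  point events with onset only);
- the dog's intake behavioural-assessment scores on seven subtests;
- a 13-item exit questionnaire from the walker.

The package detects pull episodes in the traces, computes per-walk outcome
measures, scores assessments and questionnaires, and relates outcomes to
covariates with a two-stage screened mixed-model analysis. A synthetic-study
generator with known ground truth closes the loop for validation.

## Pull-episode detection (`tension_meter`)

- **Threshold**: 0.1% of the dog's body weight expressed in kgf
  (`threshold_fraction = 0.001`), e.g. 0.02487 kgf for a 24.87 kg dog. Force
  and weight share the kilogram-force unit, so the threshold is simply
  `fraction × weight`.
- **Bouts**: maximal runs of samples strictly above the threshold.
  Sub-threshold gaps shorter than `merge_gap = 0.3 s` are merged (sensor
  flutter); merged runs shorter than `min_duration = 0.2 s` (two samples) are
  discarded. Indices are half-open `[start, end)`.
- **Phases**: each episode splits into initiation, contest, resolution.
  The *resolution* index is the tension maximum; the *contest* index is the
  maximum of the first difference (steepest sustained rise) restricted to at
  or before the resolution. Ties: take the first contiguous run of maximal
  values and return its last index. This makes a rise–plateau–decay episode
  resolve at the end of the plateau with the contest at the end of the rise,
  while two isolated equal maxima resolve at the earlier one. A perfectly
  flat episode is degenerate and collapses all phase indices to the start.
- **Attribution**: the initiator is the sign of the mean signed acceleration
  over `[start, contest)` (positive axis → dog); the winner uses
  `[resolution, end)`. Means within `accel_tie_tol = 0.01` of zero are
  *ambiguous*; ambiguous episodes are excluded from the initiator-specific
  measures by default (configurable).
- **Outcomes**: `nt_max`/`nt_mean` over all samples of the walk;
  `dt_max`/`dt_mean` (`ht_*`) over samples inside dog-initiated
  (handler-initiated) episodes; `dpf`/`hpf` are initiator-specific episode
  counts divided by walk duration. Hence `dt_max ≤ nt_max` and
  `dpf = n_dog / duration` by construction.

## Behaviour metrics and transforms (`ethogram_metrics`)

State behaviours (track, sniff, pant, tail wag, tail high) are percentages of
a denominator duration; point behaviours are per-second rates. Pant, gaze
and lip-lick can only be coded while the dog's head is in frame of the
head-mounted camera, so they use the head-visible time as denominator; all
other behaviours use total walk time. `total_verbal` and `total_body` sum
their component point events before dividing.

Intra-observer reliability uses Cohen's kappa on majority-state labels over
fixed 1 s windows. Kappa is the standard two-rater formula; when both raters
are constant and identical (chance agreement 1) kappa is defined as 1.

Each modelled outcome carries a fixed monotone transform in
`TRANSFORM_LEDGER`, applied before model fitting:

- tensions: `log10(x + 0.05)` — the offset is half the meter resolution so a
  zero tension stays finite;
- pulling frequencies: `log10(x + 1/duration)` — the offset is one event per
  walk, resolved per walk;
- behaviour percentages and rates: power transforms with exponents between
  0.3 and 0.8 per outcome; track percentage and food-reward rate are
  untransformed;
- tail-high uses power 7 evaluated on the 0–1 *proportion* scale (on the
  0–100 percentage scale the 7th power would overflow usefulness);
- questionnaire factor H uses power 10; factor D is untransformed.

`sit` cues are tallied per walk but carry no ledger entry: sit only
contributes to the total-verbal outcome in the analysis layout. The ledger
is fail-closed: `run_full_analysis` refuses outcomes without an entry.

## Scoring (`scoring`)

Assessment rubrics map observed behaviour categories to score increments per
subtest; per subtest the increments are summed and clipped to the rubric's
score range (default −5…5). The rubric itself is shelter-specific user
data; `example_rubric()` is an illustrative synthetic one for tests and
documentation only. A dog assessed more than once gets the element-wise
mean of its records.

The exit questionnaire has 13 Likert items (1–5). Negatively worded items
{2, 4, 6, 7, 8, 10, 12} are reverse-coded (`s → 6 − s`, an involution).
Factor H (handler satisfaction) is the mean of items {2, 3, 4, 5, 6, 10, 11}
and factor D (perception of the dog) the mean of {1, 7, 8, 9, 12, 13}, both
after reversal, so both stay on the 1–5 scale.

## Statistical pipeline (`stats_pipeline`)

Stage one screens every candidate predictor (seven subtest scores plus nine
demographics by default) with the bivariate Gaussian model
`transformed outcome ~ 1 + candidate`; categorical candidates are tested
with a Wald F test of their dummy block. Candidates with p < 0.2 survive,
plus any forced-in predictors. Constant candidates are excluded with a
warning. The shortlist depends only on set membership, never candidate
order.

Stage two fits a linear mixed model on the transformed outcome with the
shortlisted fixed effects and **crossed random intercepts** for dog and
walker, estimated by REML (statsmodels `MixedLM`, crossed effects realised
as variance components over a single trivial group). Fixed-effect p-values
are Wald (normal); no multiple-testing correction is applied, and cell
counts are reported so corrections can be applied downstream.
Non-convergence raises an explicit error carrying the optimizer trace; a
variance component estimated at numerical zero flags the fit singular and
reports 0.

**Zero-variance limit.** `MixedLM` cannot stably hold variance components at
exactly zero (its profiled likelihood takes `log` of them), so with
`random_effects=()` the model is computed by closed-form least-squares
normal equations (the exact zero-variance limit of REML, with the `n − p`
variance denominator and t p-values). Tests verify agreement with an
independent OLS implementation to 1e-6 relative.

Diagnostics: Shapiro–Wilk on residuals (subsampled to 5000) and on each
predicted random-effect vector; Levene's test of residual spread across four
fitted-value quantile bins. Constant residuals are reported as degenerate,
not raised.

## Synthetic-study generator (`synthetic_data`)

The generator's defaults are the study conditions; its purpose is validation
with known ground truth, not faithful re-creation of any particular shelter.

**Cohort.** Continuous covariates are truncated normals whose `(loc, scale)`
are solved numerically so that the *truncated* distribution matches the
target mean/SD — important for age, whose lower bound (2 months) sits only
1.46 SD below the mean and would otherwise bias the sample mean upward by
several months. Targets: age 44.82 ± 29.37 months, weight 24.87 ± 6.65 kg,
height 52.04 ± 6.29 cm, length 56.05 ± 5.93 cm, BCS 4.59 ± 1.07, cephalic
index 0.58 ± 0.058, 52.3% female, intake sources
stray/surrendered/returned/other at 38.74/27.93/17.12/16.22% (normalised;
the printed proportions sum to 1.0001 after rounding). Walking-difficulty
levels use probabilities (0.20, 0.40, 0.30, 0.10) — a generator choice, as
no level distribution is tabulated.

**Design.** 74 walkers × 5 walks each = 370 walks over 111 dogs; a walker
never repeats a dog, dogs are reused across walkers. A greedy rule assigns
each walker the currently least-walked dogs with random tie-breaks, keeping
per-dog usage balanced within one walk.

**Traces.** Pull events are two independent Poisson processes (dog-initiated
at 0.02/s, handler at 0.01/s by default). Event counts are drawn first and
preserved exactly whenever the walk can hold all events; placement spreads
events with a Dirichlet split of the free time and a 1 s sub-threshold guard
around each event (wider than the merge gap, so injected events never fuse).
Each event has a linear rise to amplitude `A` over 40% of its duration, a
plateau, a **single-sample jump to 1.5 A** at 70% (the contest), a short
peak hold, and a linear decay. The one-sample +50% jump guarantees — even
after 0.1 kgf quantization, which can perturb any step by at most 0.1 kgf —
that the contest-phase gradient strictly dominates every rise-phase step
whenever `A ≥ 1` kgf and duration ≥ 1.5 s; amplitudes are floored at
`max(1 kgf, 2 × threshold)` accordingly. Acceleration pulses of 0.3 s mark
onset (toward the initiator), contest (opposite) and resolution (toward the
winner, at 2× magnitude so the winner's sign survives when the contest
counter-pulse falls into the resolution window). Gaussian tension noise
defaults to 0.02 kgf — below half the meter resolution, so it rarely
survives quantization and does not create spurious episodes. Tension is
clipped to 0–100 kgf and quantized to 0.1 kgf.

**Planted effects.** `covariate_effects = {outcome: {covariate: slope}}`
acts on the transformed outcome scale (the scale stage two models), together
with crossed dog/walker random intercepts (SD 0.1 / 0.05) and Gaussian
residual (SD 0.1, with per-outcome overrides where the transformed scale is
far from unit magnitude: raw track percentage 4.0, raw food rate 0.002,
latent satisfaction 0.4). Tension effects are realised through the per-walk
dog pull rate (for `dpf`) and the event amplitude (`amplitude =
nt_target/1.5`, inverting the 1.5 A peak); behaviour effects through
inverse-transformed rates feeding Poisson counts or state durations; the
questionnaire through a latent-satisfaction ordered-threshold item model
(thresholds 1.5/2.5/3.5/4.5 with item noise SD 0.7, negatively worded items
stored un-reversed).

**What the generator does not emulate**: within-walk nonstationarity
(fatigue, route effects), correlation between behaviours beyond shared
random intercepts, missing data, coder error in ethograms, walker-level
covariates, or dog–walker interaction effects. State events are placed as
three equal intervals per behaviour; only their total duration is
calibrated.

**Randomness.** All generators are pure functions of their inputs and a
seed. Study simulation spawns independent `SeedSequence` streams for the
master draw, traces, ethograms and questionnaires (and, per walk, separate
streams for the outcome draw and the trace realisation), so adding one
consumer never perturbs another.

## Calibration problem sizes

The statistical calibration runs use the model-level outcome simulator
(`simulate_outcome_table`) rather than full 10 Hz trace synthesis per
replicate: the screen and the mixed model only see the per-walk table, and
the trace route is separately validated end to end (detection fidelity
tests and a full `run_full_analysis` study with a planted effect). Sizes:
500 screen replicates, 200 mixed-model fits × 5 noise covariates = 1000
Wald tests, and 100 coverage replicates, all at the full 370-walk design.
The planted slope for the sign-recovery check is −0.055, chosen as five
times the typical standard error of that slope at this design (measured on
an independent pilot run before the confirmatory replicates).

## Limitations

- Planted tension effects are attenuated end to end: the detectability
  floor on event amplitudes (`max(1 kgf, 2 × threshold)`) truncates the
  low-tension side, so a planted slope on the transformed `nt_max` scale
  re-emerges from full trace synthesis + detection with the correct sign
  and clear significance but a smaller magnitude. Slope-exact recovery is
  validated at the model level (`simulate_outcome_table`), where the planted
  scale and the fitted scale coincide.

- The Wald/normal p-values and 95% intervals are asymptotic; at 370 walks
  with ~110 dog and 74 walker levels they calibrate well (the acceptance
  suite checks type-I error and coverage) but small designs may not.
- The screen uses ordinary least squares and ignores the random effects;
  this is deliberate (stage one is a liberal filter), and its null inclusion
  rate is checked empirically.
- Variance components estimated at zero are truncated, flagged singular and
  reported as 0; no boundary-corrected tests are attempted.
- The detector assumes the 10 Hz regular grid of the meter; irregular
  sampling is rejected at trace construction.
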