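# Methods

## Scope and model of the data

`sleepfrag` analyzes epoch-scored rodent hypnograms: one vigilance label
(wake, NREM sleep, REM sleep) per 5-s scoring window, anchored to
zeitgeber time (ZT 0 = lights on, ZT 12 = lights off, 12:12 light/dark
cycle), with a per-epoch artifact flag. Scoring itself (from raw EEG/EMG)
is out of scope; hypnograms, per-epoch power spectral densities,
social-interaction trial times and cohort metadata are the inputs.

Artifact flags follow the scoring convention of chronic-social-defeat
sleep studies: an artifact epoch keeps its scored state for every
architecture metric and is excluded only from spectral averages. Flipping
an artifact flag therefore never changes a bout count or a percent-time
value, and removes exactly one epoch from every spectral mean — a
property the test suite asserts directly.

## Sleep-architecture metrics

A *bout* is a maximal run of consecutive epochs in one state; bouts are
obtained by run-length encoding, so their concatenation reproduces the
hypnogram exactly and consecutive bouts always differ in state.

Conventions applied uniformly (the underlying literature is silent on
most of them, so a single consistent rule is documented instead):

* Epochs are 0-indexed; all windows and bins are half-open
  `[start, end)` on a non-wrapping ZT axis, so nothing is double-counted
  at bin edges (multi-day recordings continue past ZT 24).
* A bout belongs to the window containing its **first** epoch; a
  transition (adjacent epoch pair with different labels) belongs to the
  window of its **post-transition** epoch.
* Bouts truncated by the recording boundaries count at their observed
  length. Excluding them would bias short recordings; over 24-h
  recordings the effect is negligible.
* Latency to a state is measured from a reference instant to the first
  epoch of that state at or after it, with **no** minimum bout duration
  (no persistent-sleep criterion); a state that never occurs yields a
  missing value, never zero.
* The inter-bout interval for a state is the mean gap between successive
  bouts of that state; gaps crossing a light/dark boundary, or extending
  outside the requested window, are excluded.
* Undefined quantities (mean duration with zero bouts, interval with no
  qualifying gap) propagate as `nan`, never as zero.
* No smoothing or minimum-bout filter is applied at any point; the 5-s
  scoring grid is analyzed raw.
* Recordings shorter than 24 h are accepted; phase windows clip to the
  recorded span with a logged warning.

Time courses are produced by evaluating any per-window metric over
consecutive 2-h bins (configurable) aligned to the ZT grid; a trailing
partial bin is dropped and logged. Because all bins hold the same number
of epochs, the occupancy-weighted mean of binned percent-time equals the
12-h phase value to numerical precision (asserted to 1e-9).

Structural identities used as tests: percent time over the three states
sums to 100 per window; summed bout durations equal state occupancy;
`n_bouts(S) − #(transitions into S)` is 1 when the recording starts in S
and 0 otherwise; on two-state recordings `|#(W→N) − #(N→W)| ≤ 1`. All
bout/transition/interval computations are additionally checked for exact
agreement with brute-force single-pass oracles on 1,000 seeded random
sequences.

## Spectral analysis and SWA normalization

Per-epoch PSDs use averaged periodograms with **rectangular (boxcar)
sub-windows and 20% overlap** (`scipy.signal.welch`). The sub-window
length is 2 s, fixing the 0.5-Hz frequency grid; a 5-s epoch at 250 Hz
contributes two full sub-windows. Power is density-scaled, so the
integral over the full one-sided grid approximates the signal variance.
Two numerical caveats are documented deliberately:

* With two sub-windows, the single-epoch total-power estimate carries a
  sampling SD of a few percent, and the sub-windows cover only samples
  0–900 of 1250. Unbiasedness is therefore asserted on the **mean** over
  100 seeded white-noise epochs (within 5%), with a looser 15% bound per
  epoch.
* The analysis grid spans 0.5–90 Hz (the range analyzed in this
  literature); `epoch_psd(..., fmax=fs/2)` returns the full grid when
  Parseval-type accounting is wanted.

Band power is the **mean** (not sum) of power over bins whose centers
fall in the closed band — invariant to grid extension, and 4.5 Hz
belongs to SWA (0.5–4.5 Hz). The low-delta band is 0.5–3 Hz. Theta
(5–9), beta (15–30) and slow-gamma (30–50) defaults are conventional
values, configurable per lab.

SWA normalization is per animal: every spectrum is divided by the scalar
mean SWA band power over artifact-free NREM epochs of that animal's
baseline 12-h light phase. Normalizing a baseline against itself leaves
its light-phase NREM SWA mean at exactly 1 (asserted to 1e-9). The
post-deprivation time course is the mean normalized 0.5–3-Hz power over
artifact-free NREM epochs per 2-h bin after the deprivation ends; bins
without NREM are missing.

## Social-interaction phenotyping

SI score = 100 × (interaction-zone time with target) / (time without
target). With exclusion half-width θ (default 1.0): score < 100 − θ →
susceptible; score ≥ 100 + θ → resilient; otherwise excluded. The
boundaries are intentionally asymmetric (strict below, inclusive above);
a score exactly at 100 − θ is excluded. Corner time and travel distance
are carried as descriptors only.

## Susceptibility prediction

The feature table holds one row per animal: every combination of
{percent time, bout count, mean bout duration, latency from phase start,
inter-bout interval} × {wake, NREM, REM} × {light, dark}, plus the four
transition counts (REM→wake, wake→NREM, NREM→wake, NREM→REM) per phase —
38 columns in a fixed order. The schema is a documented cross-product
rather than a hard-coded list, and includes the ten features most
predictive in defeat cohorts (`TOP10_FEATURES`). Excluded animals and
animals missing a phase are dropped; undefined values are median-imputed
(or rows dropped), logged either way.

Pipeline stages, exposed as scikit-learn estimators:

* **`FRankSelector`** — two-group ANOVA F per feature
  (between-SS / within-SS × (n − 2)); constant features score 0, zero
  within-group variance scores +inf and outranks all finite values; ties
  break lexically.
* **`VIFPruner`** — iteratively recompute each retained feature's
  variance inflation factor VIF = 1 / (1 − R²), where R² is from the
  intercept-included least-squares regression of that feature on the
  other retained features (pseudo-inverse for rank-deficient designs;
  R² numerically at 1 reports +inf), and drop the arg-max until all
  VIFs ≤ 35 (default). The implementation uses its own small lstsq
  because the common library helper omits the intercept from this
  regression. A lone surviving feature has VIF 1; a threshold that would
  eliminate everything raises.
* **`SusceptibilityClassifier`** — L2-penalized logistic regression
  (fixed C = 1.0, intercept unpenalized) on features standardized with
  the training split's statistics only, so no test-set leakage through
  scaling.

Evaluation repeats a stratified 75/25 train/test split (default 200
repeats) and reports the per-split and mean accuracy; with ~15 animals a
single split is dominated by split noise, so the repeated protocol is
the default and `n_repeats=1` (CLI `--single-split`) reproduces a
literal one-split protocol. Everything is bit-for-bit reproducible from
the seed. The accuracy-vs-k curve adds retained features in rank order.
PCA projections use standardized features with each component's sign
fixed so its largest-magnitude loading is positive.

**Known limitation — selection bias.** Ranking and pruning are performed
on the full cohort before cross-validation, mirroring the common
protocol in this literature. At n = 16 with 38 candidate features this
inflates the *null* accuracy: on cohorts whose two groups are generated
with identical parameters, the full pipeline averages ≈ 0.7 (range
0.5–0.9 across cohort draws), while a selection-free run on a-priori
fixed features centers at 0.5. The acceptance script reports both
readouts so the effect is visible; nesting the selection inside each
split would remove it at the cost of departing from the emulated
protocol.

## Synthetic cohorts

The generator produces everything the pipeline consumes from explicit
stochastic models; it emulates the *structure* of defeat-cohort
recordings, not any particular animal.

* **Semi-Markov hypnograms.** Geometric dwell times at 5-s epoch
  granularity with phase-specific means; exits follow a kernel where
  wake → NREM always, NREM splits between wake and REM, REM splits
  between wake and NREM (REM reachable only from NREM — the rodent
  convention; configurable). The continuation probability is re-drawn
  per epoch from the current phase's mean, so bouts adapt smoothly at
  ZT 12 instead of being cut. Geometric dwells are the simplest family
  with a closed-form stationary occupancy
  (μ_W / (μ_W + μ_N) for a two-state chain), which the tests verify on
  7-day runs within 3 delta-method SE.
* **Defaults** (chosen once as plausible adult-mouse values): light
  phase — wake 100 s, NREM 140 s, REM 70 s mean dwell; dark phase —
  wake 400 s, NREM 90 s, REM 55 s; NREM→wake exit probability 0.65
  (light) / 0.80 (dark); REM→wake 0.85. Artifacts: 2% of wake epochs,
  0.5% of sleep epochs (artifacts concentrate in wake movement).
* **Phenotype presets.** *Susceptible*: NREM dwell × 0.6 in both phases,
  NREM→wake exit × 1.2, light wake dwell × 0.8 — more, shorter NREM
  bouts and more NREM↔wake switching (NREM fragmentation).
  *Resilient*: dark-phase wake dwell 600 s (more dark-phase wake).
  Magnitudes are calibration choices of this generator, not measured
  effect sizes; the post-stress shift deepens fragmentation mildly
  (NREM dwell × 0.9, switching × 1.1).
* **Two-process homeostat.** Pressure S rises as
  U − (U − S₀)e^(−t/τ_rise) in wake and falls as
  L + (S₀ − L)e^(−t/τ_fall) in sleep, continuous at state changes;
  defaults L = 0.1, U = 1.0, τ_rise = 8 h, τ_fall = 2 h, S₀ = 0.5
  (rodent two-process literature values). The emitted trace satisfies
  this recursion to 1e-9 by construction and is re-derivable from any
  hypnogram with `homeostat_trace`.
* **Sleep deprivation.** Forced wake for 4 h from lights-on (every epoch
  wake), then free evolution with NREM dwell means inflated by
  1 + g·(S − L)/(U − L) (g = 1.5), so the NREM rebound decays with S.
* **Spectra.** Per epoch: 1/f background + state bump (NREM: Gaussian
  delta bump at 1.5 Hz with amplitude swa_gain·S; REM: theta bump at
  7 Hz; wake: flat broadband) × log-normal noise. swa_gain = 2.0 and the
  wake broadband floor 0.05 are set so the NREM SWA-band increment
  (≥ gain·L·0.42) exceeds the wake floor for every attainable S,
  guaranteeing NREM SWA > wake SWA at zero noise by construction.
* **SI trials.** Scores drawn uniformly in [40, 95] (susceptible) /
  [105, 170] (resilient) at zero overlap, so generated labels match the
  generating group; an overlap parameter widens both bands toward the
  exclusion zone.
* **Seeding.** One cohort seed fans out via
  `numpy.random.SeedSequence.spawn` to per-animal, per-recording
  substreams; the provenance manifest (JSON) regenerates the cohort
  byte-identically.

What the generator does **not** emulate: waveform-level EEG, ultradian
rhythms beyond the 12:12 phase switch, non-geometric dwell distributions
(real bout durations are heavier-tailed), inter-animal parameter
variability within a group, and the defeat encounters themselves.
Passing tests therefore demonstrate correctness of the *analysis* under
a known generative model, not biological claims about real cohorts.

## Problem sizes

Default test and acceptance runs use 24-h recordings (17,280 epochs),
7-day runs for stationarity checks, cohorts of 8 + 8 animals, 200
repeated splits, and 1,000 random sequences for the oracle comparison —
sizes at which all Monte-Carlo checks are stable at their stated
tolerances and the whole suite runs in well under a minute per module.
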