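# Methods

This note documents the models and procedures implemented in `breathtrack`,
the parameter choices behind them, and what the synthetic-data tests do and
do not establish about real recordings.

## Task structure

The package targets a five-condition breath-attention paradigm: passive
viewing of a pulsing circle (PasExt), passive attention to the breath with a
stationary circle (PasInt), button tracking of the circle (ActExt), button
tracking of one's own inhalations/exhalations (ActInt), and button tracking
of the circle while pacing the breath to it (ActMatch). Button 1 marks
inhalation/expansion onsets, button 2 exhalation/contraction onsets. The
default session layout is 4 blocks per condition of 30 s each; a cohort of
22 participants × 2 sessions yields 880 condition-block observations. The
block count and duration are configurable — they are a design inference,
not a protocol constant.

## Belt-signal model (synthesis)

The synthetic belt signal is `a(t)·sin(φ(t)) + ε`, where the phase φ
integrates a per-breath instantaneous frequency following a random walk
(default base 0.21 Hz, innovation SD 0.005 Hz per breath, floored at
0.05 Hz with a warning), the envelope `a(t)` interpolates a per-breath
amplitude random walk (default 1.0 a.u., SD 0.02), and ε is white noise
(SD 0.05 a.u.). Condition blocks shift the frequency (ActInt −0.024 Hz,
PasInt −0.015 Hz, ActMatch −0.002 Hz) and depth (ActInt +0.40, ActMatch
+0.29, PasInt +0.12 a.u.), reproducing the qualitative pattern that
attending to the breath slows and deepens it, with the depth ordering
PasExt ≈ ActExt < PasInt < ActMatch < ActInt.

In ActMatch blocks the breathing entrains to the circle: after one
phase-snapping entrainment breath (duration between 0.4 and 1.4 circle
cycles), inhalation onsets lock to the circle's expansion-onset grid. The
sine model's half-cycle symmetry then places exhalation onsets exactly at
contraction onsets. The entrainment breath is deliberately off-grid — a
participant cannot snap phase instantaneously — so perfect-keypress
ActMatch breath scores bottom out near 100 ms rather than zero.

Simulated keypresses anchor to the true inflections of their target (breath
events for ActInt, the circle schedule for ActExt/ActMatch) plus a constant
transduction lag (default 200 ms), Gaussian jitter (default 50 ms), and
independent misses (default 2%). Breath events up to 2 s before an ActInt
block onset still produce presses when the lagged press lands inside the
block. One master seed drives deterministic per-(participant, session)
substreams.

What the generator does **not** emulate: cardiac and CO₂ physiology,
belt-slippage and clipping artifacts, non-sinusoidal flow shapes
(inspiration is typically faster than expiration), apnea/sighs, and
learning or fatigue in the agent. Passing recovery tests therefore
demonstrates correctness of the estimators under a controlled quasi-period
model, not robustness to every artifact of scanner data.

## Belt-signal processing

- **Smoothing**: a 1 s moving average run forward and backward
  (`filtfilt`), then mean correction. Zero-phase by construction; constants
  map to zero; a 10 Hz contaminant is attenuated below 10% amplitude.
- **Z-scoring**: per run, not per trial, so RVT covariates are comparable
  across a run's trials.
- **Extrema**: `find_peaks` on the z-scored signal and its negation with a
  minimum same-type separation, then strict peak/trough alternation (the
  most extreme member of any same-type run survives), then pruning of
  adjacent peak–trough pairs closer than the amplitude threshold in
  z-units, iterated to a fixed point. Two presets: the RVT preset (0.5 SD
  prominence, 2 s separation) and the tracking preset (no prominence rule,
  1 s separation — individual breaths are unlikely to be shorter than 1 s).
- **Frequency**: argmax of the zero-padded FFT power spectrum within
  0.05–1.0 Hz (resolution ≤ 0.005 Hz). The physiological band keeps DC
  drift and broadband noise from winning; out-of-band structure is thereby
  ignored rather than clipped post hoc. A trial estimate carries a
  confidence flag: if the winning bin and its neighbours hold under 20% of
  in-band power (as for white noise), the estimate is marked
  low-confidence. The sliding estimator evaluates a 10 s window centered on
  each volume onset; at the run edges the window shifts inward so it always
  spans the full 10 s — a genuinely truncated window is biased by spectral
  leakage (≈0.025 Hz at one cycle), whereas the shifted window keeps edge
  volumes within the ±0.01 Hz recovery tolerance without imputation.
- **RVT**: linear interpolation of peak values and of trough values gives
  upper and lower envelopes; RVT is their per-sample difference, held at
  the nearest envelope value outside the first/last extremum. For a unit
  sinusoid (z-scored amplitude √2) the interior RVT is 2√2.

## Waveforms

Keypress waveforms place −1/+1 anchors at button-1/button-2 times with
linear interpolation and constant extension beyond the end anchors; the
extrapolated stretches are recorded as outside the waveform's *interior
support*. The circle follows its literal kinematic rule: rise −1→+1 over
half the respiratory period, pause at +1 for 0.2× the expansion time, fall,
pause at −1, repeat — so the full cycle is 1.2× the respiratory period.
This mildly conflicts with setting the circle's *pulse frequency* equal to
the breathing frequency; both readings are supported
(`include_pauses=False` drops the holds), with the literal rule as default.
The waveform starts at −1 (expansion onset) so button-1 anchors align with
cycle troughs; phase alignment makes the choice immaterial to accuracy
scores.

## Tracking accuracy

Phase alignment maximizes the Pearson correlation between stimulus and
keypress waveforms over integer lags in ±500 samples (±1 s at 500 Hz), each
lag normalized on its own overlap; ties break toward the smallest |lag|.
Two numerical choices matter:

1. **Interior-support masking.** Only samples inside both waveforms'
   anchor-constrained supports enter the correlation. Including the clamped
   extrapolation regions biases the lag estimate by 15–40 samples on
   trial-length segments (worst when the response leads the stimulus and
   the first anchor is lost to the trial boundary).
2. **Like-coded waveforms.** `score_session` renders the *stimulus* in the
   same ±1 anchor coding as the keypress waveform (anchors at detected
   breath extrema or at the analytic circle schedule). Correlating the raw
   trapezoidal circle-radius trace against a keypress triangle instead
   biases the lag by roughly half the pause duration (~240 ms at a 4.8 s
   period) regardless of sample size, because the two shapes' symmetry
   centers differ; a systematic offset of that size then contaminates every
   accuracy score. With like-coded waveforms the estimator is exact for a
   noise-free agent and recovers lags within a few samples under 30 ms
   jitter. `phase_align` itself is generic and accepts any waveform pair.

The accuracy statistic is the mean absolute distance (ms) from each
phase-corrected stimulus inflection to the nearest keypress, any button.
Inflections whose corrected time leaves the trial window are edge samples
and are dropped; an inflection with no nearby press contributes its full
distance to the nearest surviving press — deviations are uncapped, so miss
rates translate into large, visible error contributions rather than silent
censoring. Trials that cannot be scored (no presses, degenerate waveforms)
are returned flagged, never dropped. A strict mode restricts matching to
the semantically paired button (1↔troughs/expansions, 2↔peaks/contractions).
Under Gaussian press jitter σ and no misses, the expected error is the
folded-normal mean σ·√(2/π), which the cohort tests recover within 15% for
σ ∈ {30, 60, 100} ms. For ActInt the inflections come from detected
extrema, which sit within ~1 sample of truth on stationary signals but can
shift tens of ms where breath frequency or depth changes across a block
boundary (the smoothing window straddles an asymmetric cycle) — session
level ActInt scores for a perfect agent are therefore bounded near 5–15 ms
rather than zero.

## Confounds

The confound table has one row per acquired volume (TR default 2 s):
`volume_index, onset_s, resp_frequency_hz, rvt_au`, with frequency from the
sliding estimator on the volume grid and RVT as the mean of the
sample-level series within each TR interval. Supplied imaging-derived
columns (motion, DVARS, FD) pass through untouched; they are never computed
here. Per-trial covariates use a whole-segment FFT frequency estimate (not
the mean of sliding values) and the trial-mean RVT.

## Group statistics

Outcomes are analyzed at the condition-block level with a REML linear mixed
model: fixed effects condition + group + time + group×time, random
intercept per participant. Condition enters without an intercept and the
nuisance factors are sum-coded, so on balanced data the condition
coefficients are directly the estimated marginal means. All C(5,2) = 10
pairwise contrasts are reported with Tukey familywise adjustment through
the studentized-range distribution. Degrees of freedom use a residual-style
count, n_obs − rank(X) − (n_participants − 1); a Satterthwaite
approximation is not available for this model in the underlying library,
and with ~850 residual df the practical difference is negligible. The
omnibus condition test is a Wald F on the condition-equality contrasts; it
matches an exact participant-fixed-effects OLS F-test to numerical
precision on balanced data and holds its nominal 5% size (6.1% over 800
null replicates).

The frequency–RVT trade-off is quantified as the correlation of
participant-mean-centered frequency with participant-mean-centered RVT,
pooled across participants, with df = N_obs − 2 and a Fisher-z CI. The
repeated-measures df convention (N_obs − n_participants − 1) is available
as `method="rmcorr"` and cross-checks against an independent
repeated-measures correlation implementation; the pooled convention is the
default because it matches the df structure of the target analyses. A
block-summary generator with correlated residuals recovers an injected
within-participant r of −0.45 within ±0.06 at 880 observations.

## Power analysis

For a family of up to `n_tests` directional fMRI contrasts that must all be
significant with familywise probability ≥ 0.90: the per-test α is the
one-tailed normal tail probability at the peak-voxel Z threshold (4.53 →
2.95 × 10⁻⁶) divided by the number of contrasts (→ 2.95 × 10⁻⁷); the
per-test power requirement is 0.90^(1/10) = 0.9895. Per candidate N, the
simulation draws N participant contrast values from Normal(5.87,
0.20 + 0.22) — both printed variances perturb a participant's observed
contrast — and applies a one-tailed one-sample t-test at the corrected α;
power is the rejection fraction. The one-tailed convention is forced by the
printed α itself (the two-tailed value at Z = 4.53 would be 5.9 × 10⁻⁶).
The minimum N is the smallest candidate meeting the requirement; with the
default parameters it is 9, and the noncentral-t closed form
(power = F̄_{nct}(t_crit; N−1, √N·5.87/√0.42)) confirms the jump:
power(8) = 0.971 < 0.9895 ≤ power(9) = 0.9996. One instructive corner: at
N ≤ 3 even a tenfold effect cannot reach α = 3 × 10⁻⁷, because the t
distribution's tails at 1–2 df are heavier than any attainable statistic is
extreme — power saturation starts at df ≈ 4.

## Problem sizes in the shipped tests

The suite exercises single sessions of 5 × 4 × 30 s blocks at 500 Hz,
tracking cohorts of 4 single-condition sessions per jitter level,
mixed-model studies of 100 (coverage) and 200 (type-I) replicates of the
880-row cohort, and 20,000–50,000 Monte-Carlo draws per candidate N in the
power analysis; these sizes keep the full run under a minute while leaving
every estimate's Monte-Carlo error well inside its test tolerance.

## Known limitations

- The mixed-model df are approximate; fractional Satterthwaite df from
  specialized mixed-model software will differ slightly in small samples.
- The NCC search uses integer-sample lags; sub-sample transduction lags are
  rounded into ±1 sample (±2 ms).
- The circle's literal pause rule makes the effective pulse period 1.2× the
  respiratory period; pacing to it slows ActMatch breathing below the
  nominal condition offset. Which behaviour a given experiment intends must
  be chosen via `include_pauses`.
- RVT here is an envelope-difference score in z-units of belt stretch, a
  depth proxy; it is not calibrated to spirometric volume.
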