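# Methods

This note documents the models, numerical choices and limitations of
`riftpipe`. It is the package's own account of its science; every number
quoted here is computed by the test suite or `scripts/acceptance.py`.

## The measurement model

Two screen locations flicker at 60 and 64 Hz (one frequency per hemifield,
counterbalanced across trials as `60L/64R` vs `64L/60R`). The flicker
evokes a steady-state response in early visual cortex, phase-locked to cue
onset. Spatial attention multiplies the amplitude of the cued location's
response. The analysis must therefore detect a small, phase-locked
narrowband signal buried in broadband EEG — single-trial SNR is well below
1, and the signal becomes measurable only by accumulating phase consistency
across trials.

### Trial-set coherence

For a set of `n` trials, the EEG of each trial is band-passed at the tag
frequency ±1.9 Hz with a two-pass (zero-phase) 4th-order Butterworth filter
and Hilbert-transformed, giving instantaneous magnitude `Mx(t)` and phase
`φx(t)`. Against a unit reference sinusoid at the tag frequency, the
magnitude-squared coherence is

    coh(t) = |Σ_tr Mx My e^{iΔφ}|² / (n Σ_tr Mx² My²).

Properties (all asserted by tests): `coh ∈ [0, 1]` by Cauchy–Schwarz; for
trials that are exact copies of the reference it equals 1; under random
phase its expectation is ≈ 1/n; for a stationary narrowband signal of power
S in noise of band power N it approaches S/(S+N) as n grows. The
implementation is verified against a brute-force complex-sum oracle to
1e−12. Where the denominator is exactly zero the coherence is defined as 0.

Numerical choices:

- **Edge handling.** Samples within one settling time of an epoch edge are
  flagged invalid and excluded from averages. The settling time is
  3/bandwidth (≈ 0.79 s for the ±1.9 Hz band); epochs shorter than twice
  the settling time are rejected.
- **Spectrogram row bandwidth.** The coherence spectrogram spans 56.8 to
  67.2 Hz in 0.8 Hz steps (14 rows). A Butterworth passband of ±1.9 Hz is
  maximally flat across ±0.8 Hz, so at that row bandwidth the rows adjacent
  to a tag would capture the tag line essentially unattenuated and the 60
  and 64 Hz peaks (only 4 Hz apart) could not be resolved; worse, the 1/f
  noise slope then systematically tips the argmax toward the higher
  neighbour. Spectrogram rows are therefore filtered at ±0.95 Hz — half the
  tag band — which attenuates a line 0.8 Hz away by ~4× in power while the
  filter still settles (≈ 1.6 s) inside every epoch window. The 60/64 Hz
  *time-course* analyses keep the ±1.9 Hz band.
- **Channel selection.** The top 6 channels per participant are ranked by
  coherence averaged over the two tag frequencies and the interval during
  which both flicker patches are on screen; ties break by channel-list
  order.
- **Trial-wise response.** For mixed models the per-trial measure is the
  Hilbert magnitude averaged over the analysis interval and selected
  channels (coherence is only defined across trials).

### Alpha lateralization

Per-trial power from 3-cycle complex Morlet wavelets on an 8.0–13.4 Hz grid
in 0.2 Hz steps (28 rows; the nominal 13.5 Hz endpoint is off the 0.2 Hz
grid and excluded), converted to dB against the mean power in a pre-cue
baseline window. The group map is the per-channel difference between
right-cued and left-cued trials, band- and time-averaged; channel
significance uses a 5000-resample percentile bootstrap CI over
participants. Trial-wise lateralization is contra-minus-ipsi dB power over
the significant channels, with midline channels excluded and both
hemispheres required (an error otherwise instructs widening the selection).
The wavelet convolution is delegated to `mne.time_frequency.tfr_array_morlet`
and decimated (alpha dynamics are far slower than the 2048 Hz raw rate);
samples within half a wavelet of the epoch edges are flagged.

### Gaze

Blinks (NaN runs) are linearly interpolated where bounded by valid samples;
edge runs stay missing and are flagged. Traces are baseline-corrected to
the mean position in the 800 ms before the alignment event. A trial is
excluded when the binocular mean position is further than 2 dva from
fixation for more than 50 ms — read as *cumulative* time, the stricter and
deterministic reading of an ambiguous rule — or when its baseline deviates
more than 2 SD from the participant's mean baseline; a participant failing
fixation in more than half of the trials is excluded. The horizontal bias
is the right-cued minus left-cued mean x position, eyes averaged, smoothed
with a 10 ms (5-sample) centered moving average, reported in dva and as a
percentage of the 6 dva stimulus eccentricity.

### Resampling statistics

**Cluster permutation test** on participants × time difference traces:
pointwise two-sided one-sample t-tests (α = 0.05) define candidate clusters
as runs of consecutively significant samples spanning strictly more than
10 ms; each cluster's statistic is its summed t (t-mass). The null
distribution collects the maximum |t-mass| over random sign flips of the
participant traces (both-polarity clusters are formed; using the max
statistic gives family-wise control). A cluster is significant when its
|t-mass| exceeds the 95th percentile of the null; p = (1 + #{null ≥
observed}) / (n_perm + 1), never exactly zero. Sign flips leave
per-participant squares unchanged, so the permutation t-statistics are
computed from re-signed means against fixed second moments — this makes
10⁴ permutations cheap.

**Bootstrap mean difference**: both sets are resampled with replacement,
the difference of sample means recorded per repetition (5000 by default),
and significance declared when the 95 % percentile interval excludes zero.
The percentile interval is known to undercover slightly at small n (the
acceptance run measures ≈ 93 % coverage for two sets of 24), an inherent
property of the estimator, not of the implementation.

### QUEST staircase

The staircase maintains a posterior over log10 threshold on a 256-point
log-spaced grid over 1°–60° with a Gaussian prior (SD 0.5 log10 units,
i.e. 10 dB). The Weibull likelihood (β = 3.5, lapse Δ = 0.01, guess
γ = 0.5) is shifted, following the PsychToolbox convention, so that the
probability of a correct response at the threshold itself equals the 75 %
target; each trial is then placed at the posterior-mean threshold estimate,
clamped to the task's 3°–50° probe range. With a matched simulated
observer, accuracy over the late trials of 480-trial sessions converges to
75 % (±2 points over 100 sessions) and the threshold estimate recovers the
generating value within ±20 %.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, not
biophysics:

- **Spatial projection.** Channel names and positions come from the
  standard 64-channel BioSemi montage. Each tagged location projects onto a
  Gaussian profile (σ = 3.5 cm) centred 3.5 cm lateral to POz in the
  *contralateral* hemisphere; alpha sources are Gaussian patches (σ =
  4.5 cm) around PO7/PO8. These profiles are fixed package constants.
- **Tags.** Unit-phase sinusoids phase-locked to cue onset, amplitude
  0.8 µV, the 64 Hz tag at 0.85 relative amplitude (higher flicker rates
  evoke weaker responses). The cued location's amplitude is multiplied by
  `attention_gain` after a 0.3 s sigmoid ramp at the attention onset (at
  flicker onset for pre-cue sessions, 0.2 s after the cue otherwise).
  Experiment presets: retro-cue gain 1.0 with ±2 ms onset jitter on the tag
  phase (the aliasing of a variable stimulus–cue delay; the jitter
  measurably lowers coherence), pre-/spatial-cue gain 1.25 without jitter.
- **Alpha.** 10 Hz (±0.3 Hz per-trial jitter) with random phase and
  log-normal amplitude (6 µV), attenuated by `alpha_lateralization` (0.7)
  in the hemisphere contralateral to the cue after the attention onset.
- **Noise.** 1/f (exponent 1) spectrally shaped noise, 10 µV SD per
  channel, independent across channels; 1 µV common-mode 50 Hz line noise;
  with probability 0.02 per trial a 300 µV Gaussian transient on one
  channel (exercises artifact rejection). The tag SNR implied by these
  defaults puts best-channel coherence near 0.15–0.25 — the regime where
  coherence only emerges across trials.
- **Gaze.** Exponential drift toward the cued side (asymptote 0.06 dva,
  τ = 0.3 s), smoothed noise (0.12 dva), per-trial baseline offsets
  (SD 0.25 dva), Poisson blinks (0.08/s, 40–150 ms NaN runs), and with
  probability 0.02 a 2.5–5 dva excursion of 80–250 ms (a fixation break).
- **Behaviour.** Per-participant observer thresholds are log-normal around
  15°; ten practice trials warm the staircase before the recorded session;
  0.3 % of trials receive no response.
- **Timing.** Delays that are jittered in the real task are fixed at
  representative values so all windows are trial-invariant (the retro-cue
  aliasing is modelled as tag-phase jitter instead). Per-experiment epoch,
  baseline and analysis windows live in `riftpipe.timing`.
- **Determinism.** All randomness derives from `numpy` Generators seeded as
  `[seed, participant, stream]`; identical config + seed reproduces every
  array bit for bit.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: volume-conducted spatially correlated noise,
non-stationary alpha bursts, eye-movement and muscle artifacts with
realistic spectra, ICA-scale oculomotor contamination, inter-individual
channel-profile variability, and any nonlinearity of the steady-state
response. Effect sizes are calibrated only to reproduce qualitative regimes
(resolvable spectrogram peaks, detectable lateralization); real-data effect
magnitudes can only be estimated from actual recordings.

## Preprocessing

Average re-reference over good channels (bad channels pass through,
flagged); 0.01 Hz two-pass 2nd-order Butterworth high-pass on continuous
data (the high-pass belongs before epoching; epoch-level runs skip it);
least-squares sine/cosine regression at 50/100/150 Hz (a DFT filter —
removes stationary line noise exactly while leaving 60/64 Hz untouched);
fixed per-experiment epoch windows with half-open [start, end) sample
grids (`round(start·fs) .. round(end·fs)−1`, so the 5.4 s retro-cue window
is 11059 samples at 2048 Hz); per-trial baseline subtraction; peak-to-peak
artifact flagging at 150 µV (a deterministic stand-in for inspection-based
labelling; ICA is out of scope); participants with strictly more than 50 %
flagged trials are excluded.

## Mixed models

Per experiment, each clean trial contributes two rows (one per tag
frequency) with: cued indicator (that frequency tagged the cued location),
high-frequency indicator, trial-wise RIFT magnitude, trial-wise alpha
lateralization and signed gaze bias. Continuous predictors are z-scored
within participant (the scale of µV magnitudes and dB differences is
arbitrary; indicators stay 0/1). Fitting is delegated to statsmodels
MixedLM (REML): the full random-slope structure is attempted first and the
fit falls back to random intercepts when it fails to converge or produces
degenerate estimates; the structure used is reported. Coefficient recovery
of planted effects is asserted by tests.

## Problem sizes

Demo and test runs use reduced designs — 6 participants × 96 trials for
pipeline demos, 128 trials per gain level for the attention-recovery check,
200 null datasets × 1000 permutations for cluster-test specificity, 500
datasets for bootstrap coverage — chosen so every distributional check
retains a clear margin over its Monte-Carlo error. The full 480-trial,
15-block design is generated and used where the design itself is the
property under test and for the acceptance run's spectrogram peaks.

## Known limitations

- The continuous-file route (BrainVision round trip) stores float32; exact
  bit-reproducibility holds within, not across, the two storage routes.
- The percentile bootstrap undercovers by ~1–2 points at n = 24 (see
  above).
- With few participants the full random-slope mixed model rarely converges;
  the intercept-only fallback changes CI width, not the point estimates, in
  the regimes tested.
- Gaze exclusion interprets the 50 ms off-fixation rule cumulatively; a
  consecutive reading is configurable via `max_off_fixation_s` and the
  fixation radius.
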