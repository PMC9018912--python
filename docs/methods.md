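# Methods

This note documents the models and procedures implemented in `betadose`,
the parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## Session model

A session is one hemisphere's monopolar review: stimulation amplitude is
stepped from 0 mA upward in 0.5 mA increments up to an individual maximum,
with 60 s of rest followed by 2–3 blocks of 10 s finger tapping (10 s rest
between blocks) on every step, and a final linear ramp-down (default 23 s)
to an OFF post-DBS step. LFPs are sampled at 250 Hz in microvolts; events
are half-open intervals `[onset, onset + duration)` in seconds from
recording start. Sessions are stored in a versioned JSON dialect
(`src/betadose/schema/session.schema.json`); vendor exports are proprietary,
so converting real recordings means mapping channels, stimulation trace and
annotations onto this dialect. Accelerometer synchronization uses the
declared clock offset only; cross-correlation alignment is out of scope.

## Synthetic generator

The generator draws, per hemisphere, a `GroundTruth`: beta peak frequency
(uniform 12–19 Hz), baseline beta amplitude, per-mA suppression rate `k`,
1/f exponent, control-band amplitudes, line-noise amplitude, optional ECG
and 94 Hz aliasing artifacts, washout time constant, and the
velocity-coupling gain. The LFP is a sum of

- a Gaussian background with power spectrum ∝ f^(−χ) (χ default 1.3,
  clipped below 0.5 Hz), scaled to a target RMS (default 5 µV);
- narrowband oscillators built by shaping white noise with a Gaussian
  spectral envelope (FWHM 3 Hz for beta, similar for theta at 6.5 Hz and
  alpha at 10 Hz). Gaussian shaping keeps components spectrally compact —
  Butterworth-filtered noise leaks skirt power into neighbouring analysis
  bands — while retaining a stochastic bursting envelope. A
  `beta_burst_mod` parameter blends toward a constant-envelope sinusoid for
  studies that need a deterministic washout curve;
- 50 Hz line noise, optional aliasing tone, white measurement noise, and an
  optional triangular 80 ms QRS train for ECG contamination.

Beta amplitude at stimulation amplitude `I` is scaled by `exp(−k·I)`
instantaneously at each plateau; the last step's suppression is held during
the ramp-down, and from the moment the stimulation trace reaches 0 mA the
scale relaxes as `1 − (1−s)·exp(−t/τ)` toward baseline (`τ` =
`recovery_tau_s`, default 6 s). Only the observed recovery time, not the
kinetics, is constrained by chronic-sensing literature; the exponential
return is this package's modelling choice.

The accelerometer z-axis carries a 3 Hz sinusoidal tapping oscillation only
inside tapping blocks, with acceleration amplitude proportional to the
block's velocity `v0·(1 + c·(1 − exp(−2k·I))) + noise`, so the
integrate-and-rectify pipeline recovers the generative velocities up to a
common scale. x/y and inter-block samples are white noise. Not emulated:
tremor, dyskinesia, gait, inter-hemispheric coupling, device telemetry,
hardware saturation, non-stationary burst statistics, and realistic ECG
morphology beyond a periodic QRS-shaped template. Tests passing on this
generator therefore validate the estimators against the assumed structure;
they do not certify performance on artifacts or dynamics the generator
lacks.

## Preprocessing

Butterworth 5th-order bandpass (5–98 Hz) plus bandstop (48–52 Hz), realized
as second-order sections and applied forward-backward (zero phase) — the
downstream use is offline power estimation, not causal control. Inputs are
reflect-padded by one settle length (3/highpass-Hz seconds) and trimmed
after filtering.

Artifact screening is an automated stand-in for visual inspection, so the
scores are this package's operationalization with thresholds exposed in
configuration:

- **ECG score**: rectify the 5–40 Hz band (QRS complexes are broadband
  spikes), bandpass the envelope to the 0.5–4 Hz inter-beat modulation
  range, and take the peak of its normalized autocorrelation over lags
  0.33–2.0 s (180–30 bpm). Threshold 0.3: on synthetic sessions clean
  recordings score ≤ 0.15 and a QRS train at 3× background RMS scores
  ≥ 0.34.
- **Aliasing score**: maximum over 70–97 Hz of a bin's power divided by the
  median of its ±5 Hz neighbourhood; threshold 5. A folded stimulation tone
  stands an order of magnitude above its local floor; smooth 1/f spectra
  score below 2.

Flagged hemispheres are excluded, not cleaned.

## Spectral analysis

Morlet wavelets with 8 cycles at integer frequencies 3–97 Hz
(`mne.time_frequency.tfr_array_morlet`). The power map's time axis is
decimated by 5 (50 Hz frames): wavelet power at 8 cycles varies far more
slowly than the sample clock, so this affects runtime and memory only.
Two seconds are trimmed at segment edges (> the 1.6 s wavelet extent at
3 Hz, the slowest analyzed frequency).

Normalization divides every time-frequency cell by one scalar — the summed
time-averaged power of the 3–47 and 53–97 Hz bins, over 100 — so those bins
average to exactly 100 and the result is scale invariant. Whether the
denominator should be per whole recording or per analyzed segment is
ambiguous in practice; this package normalizes **per rest segment** so
steps are comparable within a session, and uses one **session-wide**
normalized map for the washout profile, where the shared denominator
cancels from the post/baseline ratio.

Rest spectra average the first 30 s of each step's trimmed rest interval
(shorter intervals use the full available window, recorded in
`actual_window_s`; below 10 s the interval is rejected). Band powers are
means over integer bins, inclusive at both ends — the shared 8 and 20 Hz
endpoints belong to both adjacent bands, matching the conventional
overlapping band notation.

Peak detection fits a log-log linear aperiodic floor over the reference
ranges (two passes, refitting on sub-floor points so oscillatory bumps do
not lift the fit), then takes the highest local maximum exceeding the floor
by 0.5 % (total-sum units) inside the 8–35 Hz search band; equal heights
break toward the lower frequency.

Washout: low-beta power in each of the 20 one-second windows after
cessation, divided by the pre-DBS baseline low-beta. The recovery time is
the start of the first window reaching a ratio of 0.8 sustained for 2
consecutive seconds; the 0.8/2 s criterion is this package's
operationalization of "returned to baseline".

## Movement

Velocity from z-axis acceleration: remove sub-0.5 Hz drift, integrate
(trapezoid), highpass again at 0.5 Hz (integration re-amplifies drift),
rectify, smooth with a 100-sample moving average, z-score over the whole
recording (denominator n−1). Z-scoring makes all per-block summaries
invariant to hardware scale, which is what allows pooling accelerometers
from different vendors. Block windows come from `tap_block` annotations.
Per-step means are divided by the 0 mA pre-DBS step; the trailing OFF step
is kept distinct (`POST_OFF_KEY`). A literal acceleration-to-velocity
transform is not uniquely determined by practice in this area; the
integrate-then-rectify pipeline is the package's choice, and the block-level
smoothing default is 1 s.

## Inference

- **Paired permutation test**: statistic mean(x−y); null by independent
  sign flips of the pair differences. All 2^n patterns are enumerated when
  2^n ≤ the permutation budget (exact p, no correction); otherwise
  Monte-Carlo with p = (#extreme + 1)/(n_used + 1). Default budget 10,000.
- **Mixed models**: random intercept per subject, maximum likelihood (not
  REML) so BICs are comparable across fixed-effect specifications.
  `fit_dose_model` regresses natural-log band power on amplitude (slope per
  mA); `fit_velocity_model` regresses velocity on band power. Wald tests
  use a t reference with between-within denominator degrees of freedom
  (n_obs − n_groups − 1): the asymptotic normal is anticonservative at
  cohort-sized group counts (measured null rejection 0.073 vs 0.067 with
  the t reference at α = 0.05, 10 groups × 6 steps). The reported R² is the
  marginal pseudo-R² (fixed-effects variance over fixed + random + residual
  variance). When the random-intercept variance collapses to zero the
  model degenerates to OLS, whose likelihood is used for the BIC and the
  fit is flagged unconverged. BIC counts fixed effects plus two variance
  parameters.
- **Model comparison**: ΔBIC = BIC_b − BIC_a; |ΔBIC| strictly above 6 is
  labelled strong evidence for the lower-BIC model.
- **Correlations**: Pearson when both series pass Shapiro–Wilk at
  p ≥ 0.05, else Spearman; the gate level is a package choice.

`best_effect_grouping` defines each hemisphere's best-effect step purely as
the stimulated step with maximal mean tap velocity (ties toward the lower
amplitude); in clinical practice this judgment also uses direct
observation, so this is a documented simplification.

## Validation studies and their sizes

The studies in `betadose.benchmarks` (shared by the test suite and
`scripts/acceptance.py`) use these problem sizes, chosen as the package's
standard self-validation design:

- Conservation, localization and washout studies use shortened per-step
  rests (10–20 s averaging windows) — the quantities checked are exact
  identities or deterministic crossings, not 30-s averages.
- Parameter recovery runs 10-hemisphere × 6-step cohorts, five per k in
  {0.25, 0.5, 1.0}, with 100 k=0 replicates for the null; rest 14 s with a
  10 s window. The generative configuration for these studies is
  beta-dominant with a stationary reference-range denominator (strong theta
  far from the beta band, no alpha, weak 1/f floor). This is deliberate:
  log band power saturates once the oscillation is suppressed below the
  in-band floor, and the normalization denominator itself shrinks when a
  dominant component is suppressed — both attenuate the recovered slope.
  Under paper-like defaults the recovered slope is therefore biased toward
  zero (≈ −0.4/mA for a generative −1.66/mA in the bundled cohort); this is
  a property of the band-power statistic on realistic spectra, not an
  estimator defect, and it is why recovery is certified under high-SNR
  conditions.
- The velocity-model power study uses 20 coupled cohorts; type-I
  calibration permutes power within hemispheres of an *uncoupled* cohort
  (200 refits). With a strong unmodelled step trend left in the residuals
  (a coupled cohort under permutation), the Wald test is mildly
  anticonservative (~0.09 at α = 0.05) — a known limitation of model-based
  p-values under residual structure the random intercept cannot absorb.
- The washout study uses a constant-envelope beta oscillator
  (`beta_burst_mod = 0`) and a weak floor, with τ set analytically so the
  expected ratio crosses 0.8 at 13 s. With burst-like beta, one-second
  power estimates have ~1/√(bandwidth × 1 s) ≈ 60 % relative noise, which
  makes single-seed threshold crossings uninformative about the washout
  kinetics; the recovery *rule* is still exercised on stochastic sessions
  in the end-to-end cohort.

## Known limitations

- Exclusion rates on real recordings cannot be reproduced — the screening
  thresholds were set on the simulator, and real artifact morphology is
  richer.
- The dose-model slope is interpretable as −2k only while band power is
  dominated by the oscillation (see above).
- No gamma-band or burst-duration analysis; no ECG removal; random
  intercepts only (no random slopes); no multiple-testing correction in the
  per-step permutation table.
- Peak detection searches 8–35 Hz, so with beta strongly suppressed the
  detected "peak" during stimulation may be the alpha component — mirroring
  the downward peak-frequency shift seen during effective stimulation.
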