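# betadose

Beta-band dose-response biomarker analysis for chronically sensed
subthalamic local field potentials (LFPs).

In Parkinson's disease, exaggerated 13–35 Hz (beta) oscillations in the
subthalamic nucleus are suppressed by deep brain stimulation (DBS), and the
degree of suppression tracks motor improvement. Sensing-enabled implantable
pulse generators can record LFPs *during* stimulation, which makes it
possible to step the stimulation amplitude up in 0.5 mA increments during a
monopolar review and watch the biomarker respond. `betadose` implements the
full offline analysis for such sessions, plus a synthetic-session generator
with known ground truth, for researchers developing beta-based biomarkers
and adaptive-DBS control strategies.

## What the pipeline computes

For each hemisphere's session (250 Hz bipolar LFP, a stimulation-amplitude
trace in mA, event annotations, and a merged 3-axis accelerometer):

1. **Preprocessing** — 5th-order zero-phase Butterworth bandpass 5–98 Hz and
   48–52 Hz bandstop; automated screening for ECG contamination (envelope
   periodicity at inter-beat lags) and stimulation aliasing (70–97 Hz
   spectral prominence). Contaminated hemispheres are excluded.
2. **Spectral analysis** — Morlet wavelet decomposition (8 cycles, 1 Hz
   resolution, 3–97 Hz); power expressed as % of the total sum across
   3–47 and 53–97 Hz; 30-s rest averages per stimulation step; band powers
   for theta (5–8), alpha (8–12), low beta (13–20), high beta (20–35) and
   total beta (13–35 Hz); beta-peak detection above a fitted 1/f floor;
   post-cessation washout as per-second low-beta relative to the pre-DBS
   baseline.
3. **Movement** — tapping velocity from the accelerometer z-axis
   (detrend → integrate → rectify → 100-sample moving average → z-score),
   summarized per block, per step, and relative to the 0 mA baseline.
4. **Inference** — paired sign-flip permutation tests of each step against
   baseline (exact enumeration when feasible, else 10,000 Monte-Carlo
   flips); linear mixed models with a random intercept per subject fitted
   by maximum likelihood: `log(power) ~ amplitude` for the dose-response
   (the generative square law `power ∝ exp(−2k·I)` makes log-power linear
   in amplitude) and `velocity ~ power` for the biomarker value; BIC model
   comparison (|ΔBIC| > 6 read as strong evidence); per-subject
   Pearson/Spearman correlations with a Shapiro–Wilk normality gate.

The synthetic generator produces sessions with exactly the structure this
analysis assumes — 1/f background, a burst-like beta oscillation whose
amplitude decays as `exp(−k·I)` with stimulation amplitude `I`, control
bands, line noise, optional ECG/aliasing artifacts, exponential washout
after cessation, and tapping whose velocity is coupled to the instantaneous
beta suppression — so every estimator can be validated against known
ground truth.

## Worked example

```python
from betadose.benchmarks import end_to_end_report

report = end_to_end_report(seed=0)   # 10 synthetic hemispheres, 0 -> 2.5 mA
tbl = report.band_power_table
print(tbl[(tbl.band == "low_beta") & (tbl.step_mA >= 0)][["step_mA", "mean", "sd", "n"]])
```

prints the stepwise suppression of mean low-beta power (% total sum):

```
step_mA      mean        sd   n
    0.0  5.181114  0.722883  10
    0.5  3.641772  0.604992  10
    1.0  2.572250  0.320087  10
    1.5  2.154847  0.268027  10
    2.0  1.966197  0.162186  10
    2.5  1.869639  0.121900  10
```

while mean relative tapping velocity rises from 1.00 to 2.65 over the same
steps, each stimulated step differs from baseline with permutation
p = 0.002 (the exact floor for 10 paired hemispheres), and the dose model
recovers a negative log-power slope per mA. The `examples/` directory
contains one short narrative script per capability (simulation, spectra,
dose-response, velocity biomarker, full cohort); each prints what it
computes and what the numbers mean.

A thin CLI mirrors the stages for shell use:

```bash
betadose simulate --config cohort.yaml --out data/ --seed 1
betadose run --config run.yaml      # QC -> spectra -> velocity -> stats -> report.json
```

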