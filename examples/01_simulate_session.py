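"""Simulate one monopolar-review session and inspect its structure.

Builds the stepwise 0.5 mA amplitude schedule, generates an LFP session
with dose-dependent beta suppression plus its accelerometer companion, and
prints the layout.
"""

import numpy as np

import betadose as bd

protocol = bd.make_protocol(max_amplitude_mA=2.5, step_mA=0.5)
truth = bd.GroundTruth(beta_peak_hz=16.0, suppression_k=0.83,
                       velocity_coupling_c=1.1)
session = bd.simulate_lfp(protocol, truth, seed=1)
accel = bd.simulate_accelerometer(protocol, truth, seed=2)
merged = bd.merge_accelerometer(session, accel)

print(f"amplitude schedule (mA): {protocol.step_amplitudes_mA}")
print(f"session: {merged.duration_s:.0f} s at {merged.sampling_rate_hz:.0f} Hz, "
      f"channels {[lbl for lbl, _ in merged.channels]}")
print(f"LFP rms: {np.std(merged.lfp):.2f} uV")
for label in ("rest", "tap_block", "ramp_down"):
    print(f"  {label}: {len(merged.events_labelled(label))} annotations")
print("Beta amplitude is scaled by exp(-k*I) at stimulation amplitude I mA,")
print(f"so beta power at 2.5 mA is {100 * truth.beta_scale(2.5)**2:.1f}% of baseline.")
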