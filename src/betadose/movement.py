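"""Finger-tapping velocity from the accelerometer z-axis.

Different recording setups use different accelerometer hardware, so
absolute units are meaningless; the velocity trace is z-scored over the
entire recording, which makes every per-block summary scale invariant.
The acceleration-to-velocity transform is: remove sub-0.5 Hz drift,
numerically integrate, rectify, smooth with a 100-sample moving average,
then z-score (denominator n-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate as sp_integrate
from scipy import signal as sp_signal

from .errors import DegenerateInputError, InvalidArgumentError
from .session import Annotation

#: key used for the trailing OFF (post-DBS) step in per-step tables, keeping
#: it distinct from the 0 mA pre-DBS baseline
POST_OFF_KEY = -1.0


@dataclass(frozen=True)
class MovementConfig:
    smooth_kernel_samples: int = 100
    block_smooth_s: float = 1.0
    z_axis_label: str = "accel_z"

    def __post_init__(self) -> None:
        if self.smooth_kernel_samples < 1:
            raise InvalidArgumentError("smoothing kernel must be >= 1 sample")


@dataclass
class VelocitySummary:
    """Tap velocity per block and per stimulation step, in z-units.

    ``relative_to_baseline`` divides each step's mean by the 0 mA (pre-DBS)
    step's mean, so the baseline row is exactly 1.0.
    """

    per_block: list[tuple[float, int, float]]  # (step_mA, block_index, mean velocity)
    per_step: dict[float, float]
    relative_to_baseline: dict[float, float]


def velocity_trace(z_samples: np.ndarray, fs: float,
                   cfg: MovementConfig = MovementConfig()) -> np.ndarray:
    """Z-scored rectified tapping velocity from z-axis acceleration."""
    x = np.asarray(z_samples, dtype=float)
    if len(x) < 10 * fs:
        raise InvalidArgumentError("velocity extraction requires at least 10 s of data")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant accelerometer input (zero variance)")
    sos = sp_signal.butter(2, 0.5, btype="highpass", fs=fs, output="sos")
    x = sp_signal.sosfiltfilt(sos, x)
    v = sp_integrate.cumulative_trapezoid(x, dx=1.0 / fs, initial=0.0)
    v = sp_signal.sosfiltfilt(sos, v)  # integration reintroduces drift; remove it again
    v = np.abs(v)
    kernel = np.ones(cfg.smooth_kernel_samples) / cfg.smooth_kernel_samples
    v = np.convolve(v, kernel, mode="same")
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero-variance velocity trace")
    return (v - v.mean()) / sd


def block_velocities(velocity: np.ndarray, fs: float, events: list[Annotation],
                     cfg: MovementConfig = MovementConfig()) -> VelocitySummary:
    """Mean velocity per tapping block, per step, and relative to baseline.

    Blocks are taken from ``tap_block`` annotations; each is assigned to the
    ``stim_step`` annotation containing it.  The earliest 0 mA step is the
    pre-DBS baseline.
    """
    n = len(velocity)
    steps = sorted((ev for ev in events if ev.label.startswith("stim_step:")),
                   key=lambda ev: ev.onset_s)
    if not steps:
        raise InvalidArgumentError("no stim_step annotations")
    blocks = [ev for ev in events if ev.label == "tap_block"]
    if not blocks:
        raise InvalidArgumentError("no tap_block annotations")

    per_block: list[tuple[float, int, float]] = []
    per_step_vals: dict[tuple[float, float], list[float]] = {}
    for step in steps:
        amp = float(step.label.split(":", 1)[1])
        inside = [b for b in blocks if step.onset_s - 1e-9 <= b.onset_s
                  and b.end_s <= step.end_s + 1e-9]
        for bi, b in enumerate(sorted(inside, key=lambda ev: ev.onset_s)):
            i0, i1 = int(round(b.onset_s * fs)), int(round(b.end_s * fs))
            if i0 < 0 or i1 > n:
                raise InvalidArgumentError(
                    f"tap block [{b.onset_s:.1f}, {b.end_s:.1f}) s outside the trace")
            val = float(velocity[i0:i1].mean())
            per_block.append((amp, bi, val))
            per_step_vals.setdefault((step.onset_s, amp), []).append(val)

    # keyed by (onset, amplitude) internally so the pre- and post-DBS 0 mA
    # steps stay distinct (the post one becomes POST_OFF_KEY)
    ordered = sorted(per_step_vals.items())
    per_step: dict[float, float] = {}
    seen_zero = False
    for (onset, amp), vals in ordered:
        key = amp
        if amp == 0.0:
            key = 0.0 if not seen_zero else POST_OFF_KEY
            seen_zero = True
        per_step[key] = float(np.mean(vals))
    if 0.0 not in per_step:
        raise InvalidArgumentError("missing 0 mA baseline step")
    base = per_step[0.0]
    if base == 0:
        raise DegenerateInputError("baseline step velocity is zero")
    relative = {amp: v / base for amp, v in per_step.items()}
    return VelocitySummary(per_block=per_block, per_step=per_step,
                           relative_to_baseline=relative)
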