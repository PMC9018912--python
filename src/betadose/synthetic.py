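"""Synthetic monopolar-review sessions with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a 1/f aperiodic background, a beta-band oscillation (individual
peak between 12 and 19 Hz) whose amplitude decays exponentially with the
stimulation amplitude, theta/alpha control-band components, 50 Hz line
noise, optional ECG and stimulation-aliasing artifacts, and finger-tapping
bursts whose velocity is coupled to the instantaneous beta suppression.

Because beta *amplitude* at stimulation amplitude ``I`` is scaled by
``exp(-k * I)``, beta *power* scales as ``exp(-2 k I)``: log-power is linear
in the stimulation amplitude with slope ``-2 k``, the dose-response law the
mixed-model fit is expected to recover.

Oscillatory components are amplitude-modulated narrowband noise (white
noise bandpassed to a 3 Hz band around the component frequency) rather than
pure sinusoids, so that wavelet-based power estimates face physiological
burst-like variability instead of a degenerate line spectrum.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError
from .session import AccelTrace, Annotation, SessionRecording


@dataclass(frozen=True)
class ProtocolSpec:
    """Monopolar-review schedule: stimulation steps with rest and tapping.

    ``step_amplitudes_mA`` includes a leading 0.0 (OFF pre-DBS) and a
    trailing 0.0 (OFF post-DBS, reached via a linear ramp-down).  Each step
    consists of ``rest_duration_s`` of rest followed by ``n_tap_blocks``
    finger-tapping blocks of ``tap_block_duration_s`` separated (and
    followed) by ``inter_block_rest_s`` of rest.
    """

    step_amplitudes_mA: tuple[float, ...]
    rest_duration_s: float = 60.0
    n_tap_blocks: int = 2
    tap_block_duration_s: float = 10.0
    inter_block_rest_s: float = 10.0
    ramp_down_s: float = 23.0
    sampling_rate_hz: float = 250.0

    def __post_init__(self) -> None:
        amps = tuple(float(a) for a in self.step_amplitudes_mA)
        object.__setattr__(self, "step_amplitudes_mA", amps)
        if len(amps) < 2 or amps[0] != 0.0 or amps[-1] != 0.0:
            raise InvalidArgumentError("step amplitudes must start and end with 0.0")
        if any(a < 0 for a in amps):
            raise InvalidArgumentError("step amplitudes must be non-negative")
        for name in ("rest_duration_s", "tap_block_duration_s", "inter_block_rest_s",
                     "ramp_down_s", "sampling_rate_hz"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be > 0")
        if self.n_tap_blocks < 1:
            raise InvalidArgumentError("n_tap_blocks must be >= 1")

    @property
    def step_duration_s(self) -> float:
        return (self.rest_duration_s
                + self.n_tap_blocks * (self.tap_block_duration_s + self.inter_block_rest_s))

    @property
    def duration_s(self) -> float:
        return len(self.step_amplitudes_mA) * self.step_duration_s + self.ramp_down_s

    def step_onsets_s(self) -> list[float]:
        """Onset of each step; the ramp-down precedes the trailing OFF step."""
        onsets, t = [], 0.0
        for i, _ in enumerate(self.step_amplitudes_mA):
            if i == len(self.step_amplitudes_mA) - 1:
                t += self.ramp_down_s
            onsets.append(t)
            t += self.step_duration_s
        return onsets


def make_protocol(max_amplitude_mA: float, step_mA: float = 0.5,
                  rest_duration_s: float = 60.0, n_tap_blocks: int = 2,
                  seed: int | None = None, **kwargs) -> ProtocolSpec:
    """Build the stepwise amplitude schedule 0, step, 2*step, ..., <= max, 0.

    ``seed`` is accepted for interface symmetry with the simulators but the
    schedule itself is deterministic.
    """
    if max_amplitude_mA <= 0 or step_mA <= 0:
        raise InvalidArgumentError("max_amplitude_mA and step_mA must be > 0")
    n_steps = int(np.floor(max_amplitude_mA / step_mA + 1e-9))
    if n_steps < 1:
        raise InvalidArgumentError("max amplitude below one step")
    amps = (0.0, *[round(i * step_mA, 6) for i in range(1, n_steps + 1)], 0.0)
    return ProtocolSpec(step_amplitudes_mA=amps, rest_duration_s=rest_duration_s,
                        n_tap_blocks=n_tap_blocks, **kwargs)


@dataclass(frozen=True)
class GroundTruth:
    """Generative parameters of one synthetic hemisphere.

    beta power at stimulation amplitude I is ``(beta_amp0 * exp(-suppression_k * I))**2``,
    hence log-power is linear in I with slope ``-2 * suppression_k``.
    Amplitudes are RMS microvolts of the corresponding narrowband component.
    """

    beta_peak_hz: float = 16.0
    beta_amp0: float = 2.2
    suppression_k: float = 0.83
    aperiodic_exponent: float = 1.3
    aperiodic_amp: float = 5.0
    theta_amp: float = 0.9
    alpha_amp: float = 1.6
    line_noise_amp: float = 0.4
    ecg_bpm: float = 70.0
    ecg_amp: float = 0.0
    alias_hz: float = 94.0
    alias_amp: float = 0.0
    velocity_coupling_c: float = 1.1
    recovery_tau_s: float = 6.0
    noise_sd: float = 0.5
    # tapping behaviour (burst statistics are not constrained by chronic LFP
    # literature; defaults chosen as typical UPDRS finger-tapping kinematics)
    tap_freq_hz: float = 3.0
    tap_v0: float = 1.0
    velocity_noise_sd: float = 0.05
    accel_rate_hz: float = 250.0
    beta_bw_hz: float = 3.0
    #: fraction of stochastic (burst-like) amplitude modulation in the beta
    #: oscillator: 1 = narrowband noise, 0 = constant-envelope sinusoid
    beta_burst_mod: float = 1.0

    def __post_init__(self) -> None:
        if self.suppression_k < 0:
            raise InvalidArgumentError("suppression_k must be >= 0")
        if not (12.0 <= self.beta_peak_hz <= 19.0):
            raise InvalidArgumentError("beta_peak_hz must lie in [12, 19]")
        if self.recovery_tau_s <= 0:
            raise InvalidArgumentError("recovery_tau_s must be > 0")

    def beta_scale(self, amplitude_mA: float) -> float:
        """Multiplicative beta-amplitude scale at a stimulation amplitude."""
        return float(np.exp(-self.suppression_k * amplitude_mA))

    def relative_suppression(self, amplitude_mA: float) -> float:
        """Relative beta-*power* suppression, 1 - exp(-2 k I), in [0, 1)."""
        return 1.0 - self.beta_scale(amplitude_mA) ** 2

    def block_velocity(self, amplitude_mA: float) -> float:
        """Expected tap velocity at a step (arbitrary velocity units)."""
        return self.tap_v0 * (1.0 + self.velocity_coupling_c
                              * self.relative_suppression(amplitude_mA))


# ---------------------------------------------------------------------------
# signal building blocks
# ---------------------------------------------------------------------------

def _aperiodic_background(n: int, fs: float, exponent: float, rms: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f**exponent, scaled to a target RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    # below 0.5 Hz the 1/f divergence is clipped (highpass hardware behaviour)
    shape[nz & (freqs < 0.5)] = 0.5 ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n)
    return x * (rms / np.std(x))


def _narrowband(n: int, fs: float, center_hz: float, bw_hz: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS narrowband noise: white noise spectrally shaped to a Gaussian
    power envelope of FWHM ``bw_hz`` around ``center_hz``.

    The Gaussian shaping keeps components spectrally compact (no filter
    skirts bleeding into neighbouring analysis bands) while retaining the
    stochastic bursting envelope of filtered noise.
    """
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    sigma_p = bw_hz / 2.355  # FWHM of the power spectrum
    shape = np.exp(-((freqs - center_hz) ** 2) / (4.0 * sigma_p**2))
    x = np.fft.irfft(np.fft.rfft(rng.standard_normal(n)) * shape, n)
    return x / np.std(x)


def _protocol_events(protocol: ProtocolSpec) -> list[Annotation]:
    events: list[Annotation] = []
    onsets = protocol.step_onsets_s()
    for i, (onset, amp) in enumerate(zip(onsets, protocol.step_amplitudes_mA)):
        events.append(Annotation(onset, protocol.step_duration_s, f"stim_step:{amp:g}"))
        events.append(Annotation(onset, protocol.rest_duration_s, "rest"))
        t = onset + protocol.rest_duration_s
        for _ in range(protocol.n_tap_blocks):
            events.append(Annotation(t, protocol.tap_block_duration_s, "tap_block"))
            t += protocol.tap_block_duration_s + protocol.inter_block_rest_s
        if i == len(protocol.step_amplitudes_mA) - 2:
            events.append(Annotation(onset + protocol.step_duration_s,
                                     protocol.ramp_down_s, "ramp_down"))
    return events


def stimulation_trace(protocol: ProtocolSpec) -> np.ndarray:
    """Per-sample stimulation amplitude in mA with a linear final ramp-down."""
    fs = protocol.sampling_rate_hz
    n = int(round(protocol.duration_s * fs))
    stim = np.zeros(n)
    onsets = protocol.step_onsets_s()
    step_n = int(round(protocol.step_duration_s * fs))
    for onset, amp in zip(onsets, protocol.step_amplitudes_mA):
        i0 = int(round(onset * fs))
        stim[i0: i0 + step_n] = amp
    # linear ramp between the last stimulated step and the trailing OFF step
    ramp_start = int(round((onsets[-1] - protocol.ramp_down_s) * fs))
    ramp_n = int(round(protocol.ramp_down_s * fs))
    last_amp = protocol.step_amplitudes_mA[-2]
    stim[ramp_start: ramp_start + ramp_n] = np.linspace(last_amp, 0.0, ramp_n, endpoint=False)
    return stim


def beta_amplitude_envelope(protocol: ProtocolSpec, truth: GroundTruth) -> np.ndarray:
    """Multiplicative beta-amplitude scale per sample.

    Suppression follows each plateau instantaneously; the last step's
    suppression is held during the ramp-down; from cessation (stimulation
    reaching 0 mA) the scale relaxes exponentially toward 1 with time
    constant ``recovery_tau_s``.
    """
    fs = protocol.sampling_rate_hz
    n = int(round(protocol.duration_s * fs))
    env = np.ones(n)
    onsets = protocol.step_onsets_s()
    step_n = int(round(protocol.step_duration_s * fs))
    for onset, amp in zip(onsets[:-1], protocol.step_amplitudes_mA[:-1]):
        i0 = int(round(onset * fs))
        env[i0: i0 + step_n] = truth.beta_scale(amp)
    last_amp = protocol.step_amplitudes_mA[-2]
    s_last = truth.beta_scale(last_amp)
    ramp_start = int(round((onsets[-1] - protocol.ramp_down_s) * fs))
    cess = int(round(onsets[-1] * fs))
    env[ramp_start:cess] = s_last
    t_post = np.arange(n - cess) / fs
    env[cess:] = 1.0 - (1.0 - s_last) * np.exp(-t_post / truth.recovery_tau_s)
    return env


def simulate_lfp(protocol: ProtocolSpec, truth: GroundTruth, seed: int,
                 subject_id: str = "sim", hemisphere: str = "left") -> SessionRecording:
    """Simulate one hemisphere's LFP session following the protocol.

    Deterministic for a fixed ``(protocol, truth, seed)`` triple; the seed is
    recorded in the session metadata.
    """
    fs = protocol.sampling_rate_hz
    rng = np.random.default_rng(seed)
    stim = stimulation_trace(protocol)
    n = len(stim)
    t = np.arange(n) / fs

    x = _aperiodic_background(n, fs, truth.aperiodic_exponent, truth.aperiodic_amp, rng)
    m = float(np.clip(truth.beta_burst_mod, 0.0, 1.0))
    beta = _narrowband(n, fs, truth.beta_peak_hz, truth.beta_bw_hz, rng)
    if m < 1.0:
        tone = np.sqrt(2) * np.sin(2 * np.pi * truth.beta_peak_hz * t
                                   + rng.uniform(0, 2 * np.pi))
        beta = (m * beta + (1.0 - m) * tone) / np.sqrt(m**2 + (1.0 - m) ** 2)
    x = x + truth.beta_amp0 * beta_amplitude_envelope(protocol, truth) * beta
    if truth.theta_amp > 0:
        x = x + truth.theta_amp * _narrowband(n, fs, 6.5, 2.0, rng)
    if truth.alpha_amp > 0:
        x = x + truth.alpha_amp * _narrowband(n, fs, 10.0, 2.5, rng)
    if truth.line_noise_amp > 0:
        x = x + truth.line_noise_amp * np.sqrt(2) * np.sin(
            2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
    if truth.alias_amp > 0:
        x = x + truth.alias_amp * np.sqrt(2) * np.sin(
            2 * np.pi * truth.alias_hz * t + rng.uniform(0, 2 * np.pi))
    if truth.noise_sd > 0:
        x = x + truth.noise_sd * rng.standard_normal(n)

    rec = SessionRecording(
        subject_id=subject_id,
        hemisphere=hemisphere,
        channels=[("lfp", x)],
        sampling_rate_hz=fs,
        stim_trace_mA=stim,
        events=_protocol_events(protocol),
        metadata={"seed": int(seed), "generator": "betadose.synthetic.simulate_lfp",
                  "ground_truth": dataclasses.asdict(truth)},
    )
    if truth.ecg_amp > 0:
        rec = inject_ecg_artifact(rec, truth.ecg_bpm, truth.ecg_amp)
    return rec


def simulate_accelerometer(protocol: ProtocolSpec, truth: GroundTruth,
                           seed: int) -> AccelTrace:
    """Simulate the 3-axis accelerometer companion trace.

    The z-axis carries a sinusoidal tapping oscillation only inside tapping
    blocks; its acceleration amplitude is proportional to the block's tap
    velocity ``v0 * (1 + c * relative beta suppression) + noise``, so that
    the acceleration→velocity pipeline recovers the generative velocities up
    to a common scale.  x/y and inter-block samples are white noise with
    standard deviation ``noise_sd``.
    """
    fs = truth.accel_rate_hz
    rng = np.random.default_rng(seed)
    n = int(round(protocol.duration_s * fs))
    t = np.arange(n) / fs
    x = truth.noise_sd * rng.standard_normal(n)
    y = truth.noise_sd * rng.standard_normal(n)
    z = truth.noise_sd * rng.standard_normal(n)

    onsets = protocol.step_onsets_s()
    for onset, amp in zip(onsets, protocol.step_amplitudes_mA):
        block_t = onset + protocol.rest_duration_s
        for _ in range(protocol.n_tap_blocks):
            v = truth.block_velocity(amp) + rng.normal(0.0, truth.velocity_noise_sd)
            v = max(v, 0.05 * truth.tap_v0)
            i0 = int(round(block_t * fs))
            i1 = int(round((block_t + protocol.tap_block_duration_s) * fs))
            seg_t = t[i0:i1] - t[i0]
            # acceleration amplitude v * 2*pi*f integrates to velocity amplitude v
            acc = v * 2 * np.pi * truth.tap_freq_hz * np.sin(
                2 * np.pi * truth.tap_freq_hz * seg_t + rng.uniform(0, 2 * np.pi))
            # soft 0.5 s onset/offset ramps avoid step discontinuities
            ramp = np.minimum(1.0, np.minimum(seg_t, seg_t[-1] - seg_t) / 0.5)
            z[i0:i1] += acc * ramp
            block_t += protocol.tap_block_duration_s + protocol.inter_block_rest_s
    return AccelTrace(sampling_rate_hz=fs, x=x, y=y, z=z, start_offset_s=0.0)


def inject_ecg_artifact(recording: SessionRecording, bpm: float,
                        amp: float) -> SessionRecording:
    """Return a copy of the recording with a periodic QRS-like artifact added.

    The template is a synthetic triangular QRS complex of 80 ms width
    repeated at the given heart rate on the first LFP channel.  The input
    recording is not modified.
    """
    if not (30.0 <= bpm <= 180.0):
        raise InvalidArgumentError(f"bpm must lie in [30, 180], got {bpm}")
    fs = recording.sampling_rate_hz
    n = recording.n_samples
    contaminated = np.array(recording.lfp, copy=True)
    if amp != 0.0:
        width = int(round(0.080 * fs))
        template = amp * (1.0 - np.abs(np.linspace(-1, 1, width)))
        period = 60.0 / bpm
        onset = 0.0
        while onset * fs + width < n:
            i0 = int(round(onset * fs))
            contaminated[i0: i0 + width] += template
            onset += period
    channels = [(recording.channels[0][0], contaminated)] + [
        (lbl, np.array(s, copy=True)) for lbl, s in recording.channels[1:]]
    meta = dict(recording.metadata)
    meta["ecg_injected"] = {"bpm": bpm, "amp": amp}
    return dataclasses.replace(recording, channels=channels,
                               events=list(recording.events), metadata=meta)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

DEFAULT_COHORT_RANGES: dict[str, tuple[float, float]] = {
    "beta_peak_hz": (12.0, 19.0),
    "beta_amp0": (1.8, 2.8),
    "suppression_k": (0.6, 1.1),
    "aperiodic_exponent": (1.1, 1.5),
    "velocity_coupling_c": (0.8, 1.4),
    "recovery_tau_s": (4.0, 8.0),
}


def sample_ground_truth(rng: np.random.Generator,
                        ranges: dict[str, tuple[float, float]] | None = None,
                        **fixed) -> GroundTruth:
    """Draw one hemisphere's GroundTruth with uniform draws over ``ranges``."""
    ranges = dict(DEFAULT_COHORT_RANGES if ranges is None else ranges)
    params = {name: float(rng.uniform(lo, hi)) for name, (lo, hi) in ranges.items()}
    params.update(fixed)
    return GroundTruth(**params)


def simulate_cohort(n_hemispheres: int = 10, seed: int = 0,
                    max_amplitudes_mA: tuple[float, ...] = (2.0, 2.5, 2.5, 3.0),
                    ranges: dict[str, tuple[float, float]] | None = None,
                    protocol_kwargs: dict | None = None,
                    with_accelerometer: bool = True,
                    **fixed_truth) -> list[dict]:
    """Simulate a cohort of hemispheres with per-hemisphere ground truth.

    Each hemisphere's maximum stimulation amplitude is drawn from
    ``max_amplitudes_mA`` (emulating individual side-effect thresholds, so
    group sizes shrink toward high amplitudes).  Returns a list of dicts
    with keys ``session`` (accelerometer already merged when requested),
    ``accel``, ``truth`` and ``protocol``.
    """
    from .session import merge_accelerometer

    rng = np.random.default_rng(seed)
    protocol_kwargs = protocol_kwargs or {}
    out = []
    for i in range(n_hemispheres):
        truth = sample_ground_truth(rng, ranges, **fixed_truth)
        max_amp = float(rng.choice(np.asarray(max_amplitudes_mA)))
        n_blocks = int(rng.integers(2, 4))  # 2-3 tapping blocks per step
        protocol = make_protocol(max_amp, 0.5, n_tap_blocks=n_blocks, **protocol_kwargs)
        sub = f"sub{i // 2:02d}"
        hemi = "left" if i % 2 == 0 else "right"
        sess_seed = int(rng.integers(0, 2**31 - 1))
        session = simulate_lfp(protocol, truth, sess_seed, subject_id=sub, hemisphere=hemi)
        accel = None
        if with_accelerometer:
            accel = simulate_accelerometer(protocol, truth, sess_seed + 1)
            session = merge_accelerometer(session, accel)
        out.append({"session": session, "accel": accel, "truth": truth,
                    "protocol": protocol, "hemisphere_id": f"{sub}_{hemi}"})
    return out
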