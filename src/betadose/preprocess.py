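"""Filtering and automated artifact screening.

The analysis band is isolated with a 5th-order Butterworth highpass at 5 Hz
and lowpass at 98 Hz plus a 48-52 Hz bandstop against line noise, applied
zero-phase (forward-backward) since all downstream use is offline power
estimation.  Artifact screening replaces visual inspection with two scores:
a periodicity score on the low-frequency envelope for ECG contamination and
a spectral-prominence score in the 70-97 Hz range for stimulation aliasing.
Contaminated hemispheres are excluded, not cleaned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .errors import InvalidArgumentError
from .session import SessionRecording

DEFAULT_ECG_THRESHOLD = 0.3
DEFAULT_ALIASING_THRESHOLD = 5.0


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band limits; defaults follow the analysis pipeline."""

    order: int = 5
    highpass_hz: float = 5.0
    lowpass_hz: float = 98.0
    bandstop_hz: tuple[float, float] = (48.0, 52.0)

    def __post_init__(self) -> None:
        if not (0 < self.highpass_hz < self.lowpass_hz):
            raise InvalidArgumentError("need 0 < highpass < lowpass")
        lo, hi = self.bandstop_hz
        if not (self.highpass_hz < lo < hi < self.lowpass_hz):
            raise InvalidArgumentError("bandstop must lie inside the passband")


@dataclass(frozen=True)
class QCReport:
    """Automated include/exclude decision for one hemisphere."""

    ecg_score: float
    ecg_flag: bool
    aliasing_score: float
    aliasing_flag: bool
    decision: str  # include | exclude
    reasons: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {"ecg_score": self.ecg_score, "ecg_flag": self.ecg_flag,
                "aliasing_score": self.aliasing_score, "aliasing_flag": self.aliasing_flag,
                "decision": self.decision, "reasons": list(self.reasons)}


def _settle_len(spec: FilterSpec, fs: float) -> int:
    # effective impulse settle length: generous multiple of the longest
    # time constant (the 5 Hz highpass)
    return int(round(3.0 * fs / spec.highpass_hz))


def bandpass_bandstop(samples: np.ndarray, fs: float,
                      spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Zero-phase Butterworth bandpass + line-noise bandstop.

    Realized as second-order sections for numerical stability; the input is
    reflect-padded by one settle length before forward-backward filtering
    and trimmed afterwards, so the output has the input's length.
    """
    x = np.asarray(samples, dtype=float)
    if fs <= 2 * spec.lowpass_hz:
        raise InvalidArgumentError("sampling rate must exceed twice the lowpass edge")
    pad = _settle_len(spec, fs)
    if len(x) < 3 * pad // 2:
        raise InvalidArgumentError(
            f"input too short to filter reliably: {len(x)} samples < {3 * pad // 2}")
    sos_bp = sp_signal.butter(spec.order, [spec.highpass_hz, spec.lowpass_hz],
                              btype="bandpass", fs=fs, output="sos")
    sos_bs = sp_signal.butter(spec.order, list(spec.bandstop_hz),
                              btype="bandstop", fs=fs, output="sos")
    padded = np.concatenate([x[pad:0:-1], x, x[-2: -pad - 2: -1]])
    y = sp_signal.sosfiltfilt(sos_bp, padded)
    y = sp_signal.sosfiltfilt(sos_bs, y)
    return y[pad: pad + len(x)]


def detect_ecg_contamination(samples: np.ndarray, fs: float,
                             threshold: float = DEFAULT_ECG_THRESHOLD) -> tuple[float, bool]:
    """Score cardiac contamination by the periodicity of the slow envelope.

    A QRS complex is a broadband spike, so the 5-40 Hz band is rectified
    and the envelope restricted to delta-range (0.5-4 Hz) modulation — the
    inter-beat rhythm; the score is the peak of the envelope's normalized
    autocorrelation in the physiological inter-beat lag range 0.33-2.0 s
    (180-30 bpm).  Clean recordings have a rapidly decaying envelope
    autocorrelation; a repeating QRS produces a pronounced peak at the
    inter-beat interval.
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < 20 * fs:
        raise InvalidArgumentError("ECG detection requires at least 20 s of data")
    # envelope of the 5-40 Hz band (QRS complexes are broadband spikes),
    # restricted to inter-beat modulation rates of 0.5-4 Hz
    sos_wide = sp_signal.butter(3, [5.0, 40.0], btype="bandpass", fs=fs, output="sos")
    env = np.abs(sp_signal.sosfiltfilt(sos_wide, x))
    sos_mod = sp_signal.butter(3, [0.5, 4.0], btype="bandpass", fs=fs, output="sos")
    env = sp_signal.sosfiltfilt(sos_mod, env)
    n = len(env)
    acf = sp_signal.fftconvolve(env, env[::-1], mode="full")[n - 1:]
    acf /= acf[0]
    lo, hi = int(round(0.33 * fs)), int(round(2.0 * fs))
    score = float(np.max(acf[lo: hi + 1]))
    return score, score > threshold


def detect_stim_aliasing(power_pct: np.ndarray, freqs_hz: np.ndarray,
                         threshold: float = DEFAULT_ALIASING_THRESHOLD) -> tuple[float, bool]:
    """Score stimulation aliasing as spectral prominence in 70-97 Hz.

    The score is the maximum over 70-97 Hz of a bin's power divided by the
    median power of its +-5 Hz neighbourhood (the bin itself excluded); a
    sub-Nyquist-folded stimulation tone stands far above its local 1/f
    floor, while smooth spectra score near 1.
    """
    freqs = np.asarray(freqs_hz, dtype=float)
    power = np.asarray(power_pct, dtype=float)
    if freqs.min() > 70.0 or freqs.max() < 97.0:
        raise InvalidArgumentError("spectrum must cover 70-97 Hz for aliasing screening")
    score = 0.0
    band = np.flatnonzero((freqs >= 70.0) & (freqs <= 97.0))
    for i in band:
        neigh = (np.abs(freqs - freqs[i]) <= 5.0) & (np.abs(freqs - freqs[i]) > 1e-9)
        floor = float(np.median(power[neigh]))
        if floor > 0:
            score = max(score, float(power[i]) / floor)
    return score, score > threshold


def qc_session(recording: SessionRecording, spectrum=None,
               ecg_threshold: float = DEFAULT_ECG_THRESHOLD,
               aliasing_threshold: float = DEFAULT_ALIASING_THRESHOLD) -> QCReport:
    """Run both artifact screens on a session and decide include/exclude.

    ``spectrum`` is an optional precomputed normalized rest spectrum
    (``NormalizedSpectrum``); when omitted, a Welch periodogram of the raw
    LFP is used for the aliasing screen.
    """
    ecg_score, ecg_flag = detect_ecg_contamination(
        recording.lfp, recording.sampling_rate_hz, ecg_threshold)
    if spectrum is not None:
        power, freqs = spectrum.power_pct, spectrum.freqs_hz
    else:
        freqs, power = sp_signal.welch(recording.lfp, recording.sampling_rate_hz,
                                       nperseg=int(4 * recording.sampling_rate_hz))
    alias_score, alias_flag = detect_stim_aliasing(power, freqs, aliasing_threshold)
    reasons = []
    if ecg_flag:
        reasons.append(f"ECG contamination (score {ecg_score:.2f} > {ecg_threshold})")
    if alias_flag:
        reasons.append(f"stimulation aliasing (score {alias_score:.2f} > {aliasing_threshold})")
    return QCReport(ecg_score=ecg_score, ecg_flag=ecg_flag,
                    aliasing_score=alias_score, aliasing_flag=alias_flag,
                    decision="exclude" if reasons else "include",
                    reasons=tuple(reasons))
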