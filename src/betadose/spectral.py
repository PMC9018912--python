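"""Time-frequency decomposition, normalization and band-power summaries.

The LFP is decomposed with complex Morlet wavelets (8 cycles, 1 Hz
frequency resolution from 3 to 97 Hz).  Power is expressed as percent of
the *total sum*: the summed time-averaged power across the reference
ranges 3-47 and 53-97 Hz (the 47-53 Hz gap excludes the line-noise notch).
Rest spectra are 30-s averages per stimulation step; canonical bands are
theta 5-8, alpha 8-12, low beta 13-20, high beta 20-35 and total beta
13-35 Hz (shared endpoints belong to both adjacent bands, matching the
conventional overlapping notation).

Band endpoints index integer-Hz bins inclusively at both ends.  Post-DBS
washout is summarized as low-beta power relative to the pre-DBS baseline
for each second of the first 20 s after stimulation cessation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from mne.time_frequency import tfr_array_morlet

from .errors import DegenerateInputError, InvalidArgumentError
from .session import Annotation


@dataclass(frozen=True)
class SpectralConfig:
    """Wavelet and averaging parameters.

    ``decim`` decimates the time axis of the power map (wavelet power at
    8 cycles varies far more slowly than the 250 Hz sample clock); it
    affects runtime and memory only.
    """

    freq_lo_hz: float = 3.0
    freq_hi_hz: float = 97.0
    freq_step_hz: float = 1.0
    n_cycles: float = 8.0
    norm_ranges_hz: tuple[tuple[float, float], ...] = ((3.0, 47.0), (53.0, 97.0))
    rest_window_s: float = 30.0
    recovery_window_s: float = 20.0
    edge_trim_s: float = 2.0
    decim: int = 5

    @property
    def freqs_hz(self) -> np.ndarray:
        return np.arange(self.freq_lo_hz, self.freq_hi_hz + 1e-9, self.freq_step_hz)

    def norm_mask(self, freqs: np.ndarray) -> np.ndarray:
        mask = np.zeros(len(freqs), dtype=bool)
        for lo, hi in self.norm_ranges_hz:
            mask |= (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
        return mask


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo_hz: float
    hi_hz: float


BANDS: dict[str, BandDefinition] = {
    "theta": BandDefinition("theta", 5, 8),
    "alpha": BandDefinition("alpha", 8, 12),
    "low_beta": BandDefinition("low_beta", 13, 20),
    "high_beta": BandDefinition("high_beta", 20, 35),
    "total_beta": BandDefinition("total_beta", 13, 35),
}


@dataclass
class TimeFrequencyMap:
    """Wavelet power, ``power[frequency, time]``; µV² unless normalized."""

    power: np.ndarray
    freqs_hz: np.ndarray
    times_s: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.power.shape != (len(self.freqs_hz), len(self.times_s)):
            raise InvalidArgumentError("power matrix shape must be (n_freqs, n_times)")

    def time_slice(self, t0: float, t1: float) -> "TimeFrequencyMap":
        """Sub-map over times in the half-open interval [t0, t1)."""
        m = (self.times_s >= t0 - 1e-9) & (self.times_s < t1 - 1e-9)
        return TimeFrequencyMap(self.power[:, m], self.freqs_hz, self.times_s[m],
                                self.normalized)


@dataclass
class NormalizedSpectrum:
    """Per-frequency mean power as percent of the total sum."""

    power_pct: np.ndarray
    freqs_hz: np.ndarray
    actual_window_s: float | None = None

    def renormalized(self, cfg: SpectralConfig) -> "NormalizedSpectrum":
        """Rescale so the reference-range bins sum to exactly 100."""
        mask = cfg.norm_mask(self.freqs_hz)
        total = float(np.sum(self.power_pct[mask]))
        if total <= 0:
            raise DegenerateInputError("zero total power in the reference ranges")
        return NormalizedSpectrum(self.power_pct * (100.0 / total), self.freqs_hz,
                                  self.actual_window_s)


@dataclass(frozen=True)
class PeakEstimate:
    freq_hz: float | None
    amplitude_pct: float | None
    found: bool


@dataclass(frozen=True)
class RecoveryProfile:
    """Low-beta power relative to pre-DBS baseline, per second post-cessation."""

    rel_low_beta: np.ndarray
    recovery_time_s: float | None  # None = unrecovered within the window

    @property
    def recovered(self) -> bool:
        return self.recovery_time_s is not None


def morlet_tfr(samples: np.ndarray, fs: float,
               cfg: SpectralConfig = SpectralConfig()) -> TimeFrequencyMap:
    """Morlet wavelet power map with wavelet-edge intervals trimmed.

    ``edge_trim_s`` seconds are discarded at both ends of the time axis so
    downstream averages never include convolution edge effects.
    """
    x = np.asarray(samples, dtype=float)
    freqs = cfg.freqs_hz
    longest_wavelet_s = cfg.n_cycles / freqs[0]
    if len(x) / fs <= 2 * cfg.edge_trim_s + longest_wavelet_s:
        raise InvalidArgumentError(
            f"segment of {len(x) / fs:.1f} s too short: need more than "
            f"{2 * cfg.edge_trim_s + longest_wavelet_s:.1f} s")
    power = tfr_array_morlet(x[np.newaxis, np.newaxis, :], sfreq=fs, freqs=freqs,
                             n_cycles=cfg.n_cycles, output="power",
                             decim=cfg.decim)[0, 0]
    times = np.arange(len(x))[:: cfg.decim] / fs
    keep = (times >= cfg.edge_trim_s) & (times <= times[-1] - cfg.edge_trim_s)
    return TimeFrequencyMap(power[:, keep], freqs, times[keep], normalized=False)


def normalize_total_sum(tfr: TimeFrequencyMap,
                        cfg: SpectralConfig = SpectralConfig()) -> TimeFrequencyMap:
    """Express power as % of the total sum over the reference ranges.

    Every time-frequency cell is divided by one scalar — the summed
    time-averaged power of the reference-range bins, over 100 — so the
    time-averaged normalized power over those bins sums to exactly 100 and
    the result is invariant to rescaling of the input signal.
    """
    mask = cfg.norm_mask(tfr.freqs_hz)
    denom = float(np.sum(tfr.power[mask].mean(axis=1)))
    if denom <= 0:
        raise DegenerateInputError("zero total power in the reference ranges")
    return TimeFrequencyMap(tfr.power * (100.0 / denom), tfr.freqs_hz, tfr.times_s,
                            normalized=True)


def rest_spectrum(tfr: TimeFrequencyMap, rest_interval: Annotation,
                  cfg: SpectralConfig = SpectralConfig()) -> NormalizedSpectrum:
    """Average the map over the first ``rest_window_s`` seconds of a rest interval.

    ``edge_trim_s`` is discarded at both ends of the interval first.  When
    the trimmed interval is shorter than the requested window the full
    available length is used and recorded in ``actual_window_s``; below
    10 s the interval is rejected.
    """
    t0 = rest_interval.onset_s + cfg.edge_trim_s
    t1 = rest_interval.end_s - cfg.edge_trim_s
    available = t1 - t0
    if available < 10.0:
        raise InvalidArgumentError(
            f"trimmed rest interval of {available:.1f} s is below the 10 s minimum")
    window = min(cfg.rest_window_s, available)
    sub = tfr.time_slice(t0, t0 + window)
    if sub.power.shape[1] == 0:
        raise InvalidArgumentError("rest interval does not overlap the map")
    return NormalizedSpectrum(sub.power.mean(axis=1), tfr.freqs_hz,
                              actual_window_s=float(window))


def band_power(spectrum: NormalizedSpectrum, band: BandDefinition) -> float:
    """Mean of per-frequency power over the band's integer bins, inclusive."""
    f = spectrum.freqs_hz
    if band.lo_hz < f.min() - 1e-9 or band.hi_hz > f.max() + 1e-9:
        raise InvalidArgumentError(f"band {band.name} outside spectrum coverage")
    m = (f >= band.lo_hz - 1e-9) & (f <= band.hi_hz + 1e-9)
    return float(spectrum.power_pct[m].mean())


def _aperiodic_baseline(spectrum: NormalizedSpectrum, cfg: SpectralConfig) -> np.ndarray:
    """Two-pass log-log linear fit of the aperiodic floor over the reference ranges."""
    f = spectrum.freqs_hz
    mask = cfg.norm_mask(f) & (spectrum.power_pct > 0)
    lx, ly = np.log(f[mask]), np.log(spectrum.power_pct[mask])
    coef = np.polyfit(lx, ly, 1)
    resid = ly - np.polyval(coef, lx)
    # refit on the sub-floor points so oscillatory bumps do not lift the fit
    keep = resid <= np.quantile(resid, 0.6)
    if keep.sum() >= 5:
        coef = np.polyfit(lx[keep], ly[keep], 1)
    return np.exp(np.polyval(coef, np.log(f)))


def detect_beta_peak(spectrum: NormalizedSpectrum, search_lo_hz: float = 8.0,
                     search_hi_hz: float = 35.0, prominence_pct: float = 0.5,
                     cfg: SpectralConfig = SpectralConfig()) -> PeakEstimate:
    """Highest spectral local maximum above the aperiodic floor in the search band.

    The floor is a log-log linear fit over the reference ranges; candidate
    peaks must exceed it by ``prominence_pct`` (% total sum units).  Equal
    heights break toward the lower frequency.
    """
    f = spectrum.freqs_hz
    detrended = spectrum.power_pct - _aperiodic_baseline(spectrum, cfg)
    band = np.flatnonzero((f >= search_lo_hz - 1e-9) & (f <= search_hi_hz + 1e-9))
    best_i, best_h = None, -np.inf
    for i in band:
        left = detrended[i - 1] if i > 0 else -np.inf
        right = detrended[i + 1] if i < len(f) - 1 else -np.inf
        if detrended[i] >= left and detrended[i] >= right and detrended[i] > prominence_pct:
            if detrended[i] > best_h + 1e-12:  # strict: ties keep the lower frequency
                best_i, best_h = i, detrended[i]
    if best_i is None:
        return PeakEstimate(None, None, False)
    return PeakEstimate(float(f[best_i]), float(spectrum.power_pct[best_i]), True)


def baseline_recovery(tfr_norm: TimeFrequencyMap, cessation_time_s: float,
                      baseline: NormalizedSpectrum,
                      cfg: SpectralConfig = SpectralConfig(),
                      threshold: float = 0.8,
                      sustain_s: int = 2) -> RecoveryProfile:
    """Per-second low-beta power relative to the pre-DBS baseline after cessation.

    The recovery time is the start of the first one-second window whose
    ratio reaches ``threshold`` and stays there for ``sustain_s``
    consecutive windows; if that never happens within
    ``recovery_window_s`` the profile is unrecovered.  Both numerator and
    baseline must come from the same normalized map so the normalization
    denominator cancels from the ratio.
    """
    band = BANDS["low_beta"]
    base = band_power(baseline, band)
    if base <= 0:
        raise DegenerateInputError("baseline low-beta power must be positive")
    n_win = int(cfg.recovery_window_s)
    if tfr_norm.times_s[-1] < cessation_time_s + n_win - 1e-9:
        raise InvalidArgumentError(
            f"need {n_win:.0f} s of data after cessation at {cessation_time_s:.1f} s")
    fmask = (tfr_norm.freqs_hz >= band.lo_hz - 1e-9) & (tfr_norm.freqs_hz <= band.hi_hz + 1e-9)
    ratios = np.empty(n_win)
    for j in range(n_win):
        sub = tfr_norm.time_slice(cessation_time_s + j, cessation_time_s + j + 1)
        if sub.power.shape[1] == 0:
            raise InvalidArgumentError("post-cessation window outside the map")
        ratios[j] = sub.power[fmask].mean() / base
    recovery: float | None = None
    above = ratios >= threshold
    for j in range(n_win - sustain_s + 1):
        if above[j: j + sustain_s].all():
            recovery = float(j)
            break
    return RecoveryProfile(rel_low_beta=ratios, recovery_time_s=recovery)
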