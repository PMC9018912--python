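"""Wavelet decomposition, normalization conservation, peaks, washout."""

import numpy as np
import pytest

import betadose as bd
from betadose.spectral import (BANDS, NormalizedSpectrum, SpectralConfig,
                               TimeFrequencyMap, band_power, baseline_recovery,
                               detect_beta_peak, morlet_tfr, normalize_total_sum,
                               rest_spectrum)

FS = 250.0
CFG = SpectralConfig()


def _tfr_of(x):
    return morlet_tfr(x, FS, CFG)


class TestMorletTfr:
    def test_pure_sinusoid_peaks_at_its_frequency(self):
        t = np.arange(int(40 * FS)) / FS
        tfr = _tfr_of(np.sin(2 * np.pi * 20.0 * t))
        mean_p = tfr.power.mean(axis=1)
        assert tfr.freqs_hz[np.argmax(mean_p)] == 20.0

    def test_two_tone_mixture_shows_both_maxima(self):
        t = np.arange(int(40 * FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t) + np.sin(2 * np.pi * 25.0 * t)
        mean_p = _tfr_of(x).power.mean(axis=1)
        freqs = CFG.freqs_hz
        for f0 in (10.0, 25.0):
            i = int(np.flatnonzero(freqs == f0)[0])
            assert mean_p[i] > mean_p[i - 2] and mean_p[i] > mean_p[i + 2]

    def test_zero_input_gives_zero_map(self):
        tfr = _tfr_of(np.zeros(int(40 * FS)))
        assert np.allclose(tfr.power, 0.0)

    def test_edges_trimmed(self):
        tfr = _tfr_of(np.random.default_rng(0).standard_normal(int(40 * FS)))
        assert tfr.times_s[0] >= CFG.edge_trim_s
        assert tfr.times_s[-1] <= 40.0 - CFG.edge_trim_s

    def test_too_short_segment_rejected(self):
        with pytest.raises(bd.InvalidArgumentError):
            _tfr_of(np.zeros(int(5 * FS)))


class TestNormalization:
    def test_conservation_sums_to_100(self, short_session):
        filt = bd.bandpass_bandstop(short_session.lfp, FS)
        tfr_n = normalize_total_sum(_tfr_of(filt), CFG)
        mask = CFG.norm_mask(tfr_n.freqs_hz)
        total = tfr_n.power[mask].mean(axis=1).sum()
        assert total == pytest.approx(100.0, abs=1e-6)

    def test_scale_invariance(self, short_session):
        filt = bd.bandpass_bandstop(short_session.lfp, FS)
        a = normalize_total_sum(_tfr_of(filt), CFG)
        b = normalize_total_sum(_tfr_of(filt * 10.0), CFG)
        assert np.allclose(a.power, b.power, rtol=1e-9)

    def test_zero_power_rejected(self):
        tfr = TimeFrequencyMap(np.zeros((95, 10)), CFG.freqs_hz, np.arange(10.0))
        with pytest.raises(bd.DegenerateInputError):
            normalize_total_sum(tfr, CFG)

    def test_single_bin_concentration(self):
        power = np.zeros((95, 10))
        power[13] = 5.0  # all power in one in-range bin
        tfr = TimeFrequencyMap(power, CFG.freqs_hz, np.arange(10.0))
        out = normalize_total_sum(tfr, CFG)
        assert out.power[13].mean() == pytest.approx(100.0)


class TestRestSpectrum:
    def test_equals_windowed_time_average(self):
        rng = np.random.default_rng(3)
        tfr = _tfr_of(rng.standard_normal(int(60 * FS)))
        rest = bd.Annotation(0.0, 60.0, "rest")
        spec = rest_spectrum(tfr, rest, CFG)
        t0 = CFG.edge_trim_s
        manual = tfr.time_slice(t0, t0 + CFG.rest_window_s).power.mean(axis=1)
        assert np.allclose(spec.power_pct, manual, atol=1e-9)
        assert spec.actual_window_s == 30.0

    def test_short_interval_uses_available_window(self):
        tfr = _tfr_of(np.random.default_rng(4).standard_normal(int(24 * FS)))
        spec = rest_spectrum(tfr, bd.Annotation(0.0, 24.0, "rest"), CFG)
        assert spec.actual_window_s == pytest.approx(20.0)

    def test_below_minimum_rejected(self):
        tfr = _tfr_of(np.random.default_rng(5).standard_normal(int(40 * FS)))
        with pytest.raises(bd.InvalidArgumentError):
            rest_spectrum(tfr, bd.Annotation(0.0, 12.0, "rest"), CFG)

    def test_disjoint_windows_of_stationary_signal_agree(self):
        rng = np.random.default_rng(6)
        x = bd.GroundTruth().aperiodic_amp * rng.standard_normal(int(100 * FS))
        tfr = _tfr_of(x)
        s1 = rest_spectrum(tfr, bd.Annotation(0.0, 40.0, "rest"), CFG).renormalized(CFG)
        s2 = rest_spectrum(tfr, bd.Annotation(50.0, 50.0, "rest"), CFG).renormalized(CFG)
        # 30 s averages of a stationary process: per-bin sampling error is a
        # few percent of the (flat) per-bin level
        assert np.allclose(s1.power_pct, s2.power_pct,
                           atol=5 * s1.power_pct.mean() / np.sqrt(30))


class TestBandPower:
    def test_flat_spectrum_band_mean(self):
        spec = NormalizedSpectrum(np.ones(95), CFG.freqs_hz)
        for band in BANDS.values():
            assert band_power(spec, band) == pytest.approx(1.0)

    def test_concentrated_power_ranks_bands(self):
        p = np.zeros(95)
        p[CFG.freqs_hz == 16.0] = 100.0
        spec = NormalizedSpectrum(p, CFG.freqs_hz)
        assert band_power(spec, BANDS["low_beta"]) > band_power(spec, BANDS["high_beta"])

    def test_band_outside_coverage_rejected(self):
        spec = NormalizedSpectrum(np.ones(95), CFG.freqs_hz)
        from betadose.spectral import BandDefinition
        with pytest.raises(bd.InvalidArgumentError):
            band_power(spec, BandDefinition("hf", 90, 120))

    def test_shared_endpoint_belongs_to_both_bands(self):
        p = np.zeros(95)
        p[CFG.freqs_hz == 20.0] = 10.0
        spec = NormalizedSpectrum(p, CFG.freqs_hz)
        assert band_power(spec, BANDS["low_beta"]) > 0
        assert band_power(spec, BANDS["high_beta"]) > 0


class TestPeakDetection:
    def _one_over_f(self):
        return 100.0 / CFG.freqs_hz**1.3

    def test_gaussian_bump_on_one_over_f(self):
        f = CFG.freqs_hz
        p = self._one_over_f() + 3.0 * np.exp(-((f - 16.0) ** 2) / 4.0)
        peak = detect_beta_peak(NormalizedSpectrum(p, f))
        assert peak.found and abs(peak.freq_hz - 16.0) <= 1.0

    def test_monotone_spectrum_has_no_peak(self):
        peak = detect_beta_peak(NormalizedSpectrum(self._one_over_f(), CFG.freqs_hz))
        assert not peak.found and peak.freq_hz is None

    def test_larger_of_two_bumps_wins(self):
        f = CFG.freqs_hz
        p = (self._one_over_f() + 2.0 * np.exp(-((f - 16.0) ** 2) / 4.0)
             + 4.0 * np.exp(-((f - 25.0) ** 2) / 4.0))
        assert detect_beta_peak(NormalizedSpectrum(p, f)).freq_hz == 25.0

    def test_equal_heights_tie_breaks_low(self):
        f = CFG.freqs_hz
        base = np.full_like(f, 2.0)
        p = base.copy()
        p[f == 16.0] += 3.0
        p[f == 25.0] += 3.0
        assert detect_beta_peak(NormalizedSpectrum(p, f)).freq_hz == 16.0

    def test_simulated_peak_recovered(self):
        from betadose.benchmarks import oscillation_probe_spectrum
        spec = oscillation_probe_spectrum(16.0, seed=9)
        peak = detect_beta_peak(spec)
        assert peak.found and abs(peak.freq_hz - 16.0) <= 1.0


class TestBaselineRecovery:
    def _map_with_ratio(self, ratio_fn):
        """Constant-baseline map whose low-beta follows ratio_fn(t) after t=0."""
        times = np.arange(0.0, 25.0, 0.1)
        power = np.ones((95, len(times)))
        band = (CFG.freqs_hz >= 13) & (CFG.freqs_hz <= 20)
        power[np.ix_(band, np.arange(len(times)))] = ratio_fn(times)
        tfr = TimeFrequencyMap(power, CFG.freqs_hz, times, normalized=True)
        baseline = NormalizedSpectrum(np.ones(95), CFG.freqs_hz)
        return tfr, baseline

    def test_immediate_recovery(self):
        tfr, base = self._map_with_ratio(lambda t: np.ones_like(t))
        prof = baseline_recovery(tfr, 0.0, base, CFG)
        assert prof.recovery_time_s <= 1.0

    def test_sustained_suppression_is_unrecovered(self):
        tfr, base = self._map_with_ratio(lambda t: np.full_like(t, 0.3))
        prof = baseline_recovery(tfr, 0.0, base, CFG)
        assert not prof.recovered and prof.recovery_time_s is None

    def test_exponential_return_crosses_at_expected_second(self):
        from betadose.benchmarks import recovery_tau_for_crossing
        tau = recovery_tau_for_crossing(0.83, 2.5, t_cross_s=7.0)
        s = np.exp(-0.83 * 2.5)
        tfr, base = self._map_with_ratio(
            lambda t: (1 - (1 - s) * np.exp(-t / tau)) ** 2)
        prof = baseline_recovery(tfr, 0.0, base, CFG)
        assert prof.recovery_time_s == pytest.approx(7.0, abs=1.0)

    def test_insufficient_post_data_rejected(self):
        tfr, base = self._map_with_ratio(lambda t: np.ones_like(t))
        with pytest.raises(bd.InvalidArgumentError):
            baseline_recovery(tfr, 10.0, base, CFG)
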