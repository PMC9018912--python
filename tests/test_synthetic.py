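"""Generator contracts: protocol layout, determinism, generative laws."""

import numpy as np
import pytest
from scipy import signal as sp_signal

import betadose as bd
from betadose.synthetic import beta_amplitude_envelope, stimulation_trace
from conftest import SHORT_PROTOCOL_KW


class TestMakeProtocol:
    @pytest.mark.parametrize("max_amp,expected", [
        (2.5, (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 0.0)),
        (0.5, (0.0, 0.5, 0.0)),
        (2.2, (0.0, 0.5, 1.0, 1.5, 2.0, 0.0)),  # floors to the step grid
    ])
    def test_amplitude_schedule(self, max_amp, expected):
        proto = bd.make_protocol(max_amp, 0.5)
        assert proto.step_amplitudes_mA == expected

    @pytest.mark.parametrize("bad", [(-1.0, 0.5), (2.0, 0.0), (0.0, 0.5)])
    def test_invalid_arguments(self, bad):
        with pytest.raises(bd.InvalidArgumentError):
            bd.make_protocol(*bad)

    def test_schedule_layout(self, short_protocol):
        onsets = short_protocol.step_onsets_s()
        assert onsets[0] == 0.0
        assert np.allclose(np.diff(onsets[:-1]), short_protocol.step_duration_s)
        # ramp-down inserted before the trailing OFF step
        assert onsets[-1] == pytest.approx(
            onsets[-2] + short_protocol.step_duration_s + short_protocol.ramp_down_s)


class TestStimTraceAndEnvelope:
    def test_stim_plateau_values(self, short_protocol):
        stim = stimulation_trace(short_protocol)
        fs = short_protocol.sampling_rate_hz
        for onset, amp in zip(short_protocol.step_onsets_s(),
                              short_protocol.step_amplitudes_mA):
            mid = int((onset + 2.0) * fs)
            assert stim[mid] == amp

    def test_ramp_is_linear_to_zero(self, short_protocol):
        stim = stimulation_trace(short_protocol)
        fs = short_protocol.sampling_rate_hz
        t_off = short_protocol.step_onsets_s()[-1]
        ramp = stim[int((t_off - short_protocol.ramp_down_s) * fs): int(t_off * fs)]
        assert ramp[0] == pytest.approx(short_protocol.step_amplitudes_mA[-2])
        assert np.all(np.diff(ramp) <= 1e-12)
        assert stim[int(t_off * fs)] == 0.0

    def test_envelope_follows_suppression_and_recovers(self, short_protocol):
        truth = bd.GroundTruth(suppression_k=1.0, recovery_tau_s=4.0)
        env = beta_amplitude_envelope(short_protocol, truth)
        fs = short_protocol.sampling_rate_hz
        for onset, amp in zip(short_protocol.step_onsets_s()[:-1],
                              short_protocol.step_amplitudes_mA[:-1]):
            mid = int((onset + 5.0) * fs)
            assert env[mid] == pytest.approx(np.exp(-amp))
        # exponential return after cessation
        t_off = short_protocol.step_onsets_s()[-1]
        s_last = np.exp(-short_protocol.step_amplitudes_mA[-2])
        for dt in (4.0, 8.0):
            expected = 1 - (1 - s_last) * np.exp(-dt / 4.0)
            assert env[int((t_off + dt) * fs)] == pytest.approx(expected, rel=1e-3)


class TestSimulateLfp:
    def test_deterministic_for_fixed_seed(self, short_protocol, default_truth):
        a = bd.simulate_lfp(short_protocol, default_truth, seed=7)
        b = bd.simulate_lfp(short_protocol, default_truth, seed=7)
        assert np.array_equal(a.lfp, b.lfp)
        assert np.array_equal(a.stim_trace_mA, b.stim_trace_mA)

    def test_different_seeds_differ(self, short_protocol, default_truth):
        a = bd.simulate_lfp(short_protocol, default_truth, seed=7)
        b = bd.simulate_lfp(short_protocol, default_truth, seed=8)
        assert not np.array_equal(a.lfp, b.lfp)

    def _step_beta_power(self, session, protocol, truth):
        """Raw beta-band power per step via a narrow bandpass around the peak."""
        fs = protocol.sampling_rate_hz
        lo, hi = truth.beta_peak_hz - 2, truth.beta_peak_hz + 2
        sos = sp_signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        y = sp_signal.sosfiltfilt(sos, session.lfp)
        powers = []
        for onset, amp in zip(protocol.step_onsets_s()[:-1],
                              protocol.step_amplitudes_mA[:-1]):
            seg = y[int((onset + 1) * fs): int((onset + protocol.rest_duration_s) * fs)]
            powers.append(np.mean(seg**2))
        return np.array(powers), np.array(protocol.step_amplitudes_mA[:-1])

    def test_no_dose_effect_when_k_zero(self):
        proto = bd.make_protocol(2.5, 0.5, **SHORT_PROTOCOL_KW)
        truth = bd.GroundTruth(suppression_k=0.0, beta_amp0=3.0, aperiodic_amp=1.0,
                               noise_sd=0.2)
        powers, _ = self._step_beta_power(bd.simulate_lfp(proto, truth, seed=3),
                                          proto, truth)
        assert powers.max() / powers.min() < 1.6  # equal within sampling error

    def test_log_power_slope_is_minus_two_k(self):
        # generative dose-response law, averaged over several long simulations
        proto = bd.make_protocol(2.5, 0.5, rest_duration_s=40.0,
                                 tap_block_duration_s=2.0, inter_block_rest_s=2.0,
                                 ramp_down_s=5.0)
        truth = bd.GroundTruth(suppression_k=1.0, beta_amp0=4.0, aperiodic_amp=0.3,
                               theta_amp=0.3, alpha_amp=0.3, noise_sd=0.1,
                               line_noise_amp=0.0)
        slopes = []
        for seed in range(4):
            powers, amps = self._step_beta_power(
                bd.simulate_lfp(proto, truth, seed=seed), proto, truth)
            slopes.append(np.polyfit(amps, np.log(powers), 1)[0])
        assert np.mean(slopes) == pytest.approx(-2.0, rel=0.10)

    def test_aperiodic_exponent_recovered_without_oscillators(self):
        proto = bd.make_protocol(0.5, 0.5, rest_duration_s=60.0,
                                 tap_block_duration_s=2.0, inter_block_rest_s=2.0,
                                 ramp_down_s=5.0)
        exps = []
        for seed in range(3):
            truth = bd.GroundTruth(suppression_k=0.0, beta_amp0=0.0, theta_amp=0.0,
                                   alpha_amp=0.0, line_noise_amp=0.0, noise_sd=0.0,
                                   aperiodic_exponent=1.3)
            sess = bd.simulate_lfp(proto, truth, seed=seed)
            f, p = sp_signal.welch(sess.lfp, proto.sampling_rate_hz, nperseg=4096)
            m = (f >= 5) & (f <= 45)
            exps.append(-np.polyfit(np.log(f[m]), np.log(p[m]), 1)[0])
        assert np.mean(exps) == pytest.approx(1.3, abs=0.2)


class TestSimulateAccelerometer:
    def test_z_outside_blocks_is_pure_noise(self, short_protocol):
        truth = bd.GroundTruth(noise_sd=0.4)
        accel = bd.simulate_accelerometer(short_protocol, truth, seed=5)
        fs = truth.accel_rate_hz
        rest = accel.z[: int(10 * fs)]  # inside the first rest period
        assert np.std(rest) == pytest.approx(0.4, rel=0.1)
        assert np.std(accel.x) == pytest.approx(0.4, rel=0.1)

    def test_velocity_coupling_zero_gives_equal_blocks(self, short_protocol):
        truth = bd.GroundTruth(velocity_coupling_c=0.0, velocity_noise_sd=0.0,
                               noise_sd=0.05)
        accel = bd.simulate_accelerometer(short_protocol, truth, seed=5)
        fs = truth.accel_rate_hz
        amps = []
        for onset in short_protocol.step_onsets_s():
            i0 = int((onset + short_protocol.rest_duration_s + 0.6) * fs)
            amps.append(np.std(accel.z[i0: i0 + int(0.8 * fs)]))
        assert max(amps) / min(amps) < 1.1

    def test_expected_block_velocity_monotone_in_dose(self):
        truth = bd.GroundTruth(velocity_coupling_c=1.0, suppression_k=0.8)
        doses = np.arange(0, 3, 0.5)
        v = [truth.block_velocity(a) for a in doses]
        assert np.all(np.diff(v) > 0)


class TestInjectEcg:
    def test_zero_amplitude_is_identity(self, short_session):
        out = bd.inject_ecg_artifact(short_session, bpm=60, amp=0.0)
        assert np.array_equal(out.lfp, short_session.lfp)

    def test_input_not_modified(self, short_session):
        before = short_session.lfp.copy()
        bd.inject_ecg_artifact(short_session, bpm=60, amp=50.0)
        assert np.array_equal(short_session.lfp, before)

    def test_autocorrelation_peak_at_beat_interval(self, short_session):
        out = bd.inject_ecg_artifact(short_session, bpm=60, amp=80.0)
        fs = out.sampling_rate_hz
        x = out.lfp - out.lfp.mean()
        n = len(x)
        acf = sp_signal.fftconvolve(x, x[::-1], mode="full")[n - 1:]
        acf /= acf[0]
        lag1 = int(fs)  # 60 bpm -> 1.0 s
        window = acf[lag1 - 25: lag1 + 26]
        assert np.argmax(window) == pytest.approx(25, abs=3)
        assert window.max() > acf[int(0.5 * fs)]

    @pytest.mark.parametrize("bpm", [20, 200])
    def test_bpm_range_enforced(self, short_session, bpm):
        with pytest.raises(bd.InvalidArgumentError):
            bd.inject_ecg_artifact(short_session, bpm=bpm, amp=1.0)
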