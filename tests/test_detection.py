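"""Complex cross-correlation detection: envelopes, noise floors, peaks."""

import numpy as np
import pytest
from scipy.signal import hilbert

from speechdpoae import (
    ComplexCorrelogram, DegenerateAmplitudeError, DPOAEPeak, EarCanalRecording,
    EmissionSpec, NoStimulusLockError, complex_xcorr, correct_delay,
    detect_trial_peak, detection_rate, estimate_hardware_delay, grand_average,
    noise_floor, simulate_recording, white_noise_rms_for_inband_snr,
)

FS = 44_100


def make_correlogram(lags_ms, envelope):
    """Correlogram with a prescribed (real, nonnegative) envelope."""
    return ComplexCorrelogram(lags_ms=np.asarray(lags_ms, float),
                              values=np.asarray(envelope, float).astype(complex),
                              fs=FS)


def percentile_oracle(values, q):
    """Brute-force sort-based linear-interpolation percentile."""
    v = np.sort(np.asarray(values, float))
    pos = (q / 100.0) * (v.size - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, v.size - 1)
    return v[lo] + (pos - lo) * (v[hi] - v[lo])


class TestComplexXcorr:
    def test_autocorrelation_peaks_at_zero(self, small_stimulus):
        wdp = small_stimulus.pairs[0].w_dp
        rec = EarCanalRecording(samples=wdp, fs=small_stimulus.fs)
        cg = complex_xcorr(rec, wdp)
        assert cg.lags_ms[np.argmax(cg.envelope)] == pytest.approx(0.0, abs=1e-9)

    def test_analytic_rotation_identity(self, small_stimulus):
        wdp = small_stimulus.pairs[0].w_dp
        rotated = np.real(hilbert(wdp) * np.exp(1j * np.pi / 2))
        cg0 = complex_xcorr(EarCanalRecording(samples=wdp, fs=FS), wdp)
        cg1 = complex_xcorr(EarCanalRecording(samples=rotated, fs=FS), wdp)
        i0 = np.argmax(cg0.envelope)
        assert cg1.envelope[i0] == pytest.approx(cg0.envelope[i0], rel=0.01)
        # the rotation moved the correlation into the imaginary part
        assert abs(cg1.values[i0].real) < 0.05 * cg1.envelope[i0]

    def test_noise_has_no_systematic_zero_lag_peak(self, tiny_stimulus):
        wdp = tiny_stimulus.pairs[0].w_dp
        lags = []
        for seed in range(40):
            rec = simulate_recording(tiny_stimulus, [], noise_rms=1e-3, seed=seed)
            cg = complex_xcorr(rec, wdp)
            peak = detect_trial_peak(cg, noise_floor(cg))
            lags.append(peak.delay_ms)
        lags = np.array(lags)
        # peak lags scatter over the search window instead of piling at 0
        assert np.std(lags) > 0.5
        assert abs(np.median(lags) - 1.0) < 2.5

    def test_silent_template_rejected(self, tiny_stimulus):
        rec = EarCanalRecording(samples=np.zeros(FS), fs=FS)
        with pytest.raises(DegenerateAmplitudeError):
            complex_xcorr(rec, np.zeros(FS))

    def test_pearson_mode_bounded(self, small_stimulus):
        wdp = small_stimulus.pairs[0].w_dp
        rec = EarCanalRecording(samples=wdp, fs=FS)
        cg = complex_xcorr(rec, wdp, mode="pearson")
        i = np.argmax(cg.envelope)
        assert cg.lags_ms[i] == pytest.approx(0.0, abs=1e-9)
        assert cg.values[i].real == pytest.approx(1.0, abs=0.01)


class TestNoiseFloor:
    def test_constant_envelope(self):
        lags = np.linspace(-750, 750, 3001)
        ns = noise_floor(make_correlogram(lags, np.full(lags.size, 0.7)))
        assert ns.noise_max == pytest.approx(0.7)
        assert ns.noise_p97 == pytest.approx(0.7)

    def test_percentile_matches_bruteforce_oracle(self, rng):
        lags = np.linspace(-750, 750, 4001)
        env = rng.uniform(0.0, 1.0, lags.size)
        cg = make_correlogram(lags, env)
        ns = noise_floor(cg)
        mask = ((lags >= -750) & (lags <= -70)) | ((lags >= 70) & (lags <= 750))
        assert ns.noise_p97 == pytest.approx(percentile_oracle(env[mask], 97.0),
                                             abs=1e-12)
        assert ns.noise_max == env[mask].max()

    def test_spike_inside_70ms_ignored(self):
        lags = np.linspace(-750, 750, 3001)
        env = np.full(lags.size, 0.1)
        env[np.argmin(np.abs(lags))] = 5.0
        ns = noise_floor(make_correlogram(lags, env))
        assert ns.noise_max == pytest.approx(0.1)

    def test_insufficient_coverage_rejected(self):
        lags = np.linspace(-10, 10, 101)
        cg = make_correlogram(lags, np.ones(lags.size))
        cg.lags_ms = lags  # ±10 ms cannot host scaled windows below ±70/750
        with pytest.warns(UserWarning):
            ns = noise_floor(cg)
        assert ns.window_definition[0][0] == pytest.approx(-10.0)


class TestTrialPeak:
    def test_out_of_window_emission_flagged(self, small_stimulus):
        """An emission well outside the search window is not declared
        significant inside it; the excess energy is flagged instead."""
        wdp = small_stimulus.pairs[0].w_dp
        noise = white_noise_rms_for_inband_snr(wdp, small_stimulus.fs, 10.0,
                                               gain=1e-3)
        rec = simulate_recording(small_stimulus,
                                 [EmissionSpec(0, gain=1e-3, delay_ms=30.0)],
                                 noise_rms=noise, seed=1)
        cg = complex_xcorr(rec, wdp)
        peak = detect_trial_peak(cg, noise_floor(cg))
        # the 30 ms peak itself never enters the reported delay ...
        assert peak.delay_ms <= 4.0
        assert cg.lags_ms[np.argmax(cg.envelope)] == pytest.approx(30.0, abs=0.25)
        # ... the in-window amplitude is only residual tail/noise ...
        assert peak.amplitude < 0.2 * cg.envelope.max()
        # ... and the stray energy is surfaced in the diagnostics
        assert peak.diagnostics == "out-of-window energy"

    def test_tie_breaks_to_smallest_lag(self):
        lags = np.linspace(-750, 750, 66151)
        env = np.full(lags.size, 0.1)
        window = (lags >= -2) & (lags <= 4)
        env[window] = 0.5  # plateau: every in-window lag ties
        peak = detect_trial_peak(make_correlogram(lags, env),
                                 noise_floor(make_correlogram(lags, env)))
        assert peak.delay_ms == pytest.approx(lags[window][0])


class TestGrandAverage:
    def test_mean_of_identical_is_member(self, small_stimulus):
        wdp = small_stimulus.pairs[0].w_dp
        rec = EarCanalRecording(samples=wdp, fs=FS)
        cg = complex_xcorr(rec, wdp)
        lags, avg, peak, ns = grand_average([cg, cg, cg])
        assert np.allclose(avg, cg.envelope)
        assert peak.significant and peak.delay_ms == pytest.approx(0.0, abs=1e-9)

    def test_mismatched_grids_rejected(self):
        a = make_correlogram(np.linspace(-750, 750, 1001), np.ones(1001))
        b = make_correlogram(np.linspace(-750, 750, 2001), np.ones(2001))
        with pytest.raises(ValueError, match="lag grids"):
            grand_average([a, b])

    def test_averaging_gain_beats_single_trials(self, tiny_stimulus):
        """At low per-trial SNR the grand average is significant even when
        many single trials are not (noise averages as 1/sqrt(N))."""
        wdp = tiny_stimulus.pairs[0].w_dp
        gain = 1e-3
        noise = white_noise_rms_for_inband_snr(wdp, tiny_stimulus.fs, 0.0, gain=gain)
        cgs, single_sig = [], 0
        for seed in range(40):
            rec = simulate_recording(tiny_stimulus,
                                     [EmissionSpec(0, gain=gain, delay_ms=1.0)],
                                     noise_rms=noise, seed=seed)
            cg = complex_xcorr(rec, wdp)
            single_sig += detect_trial_peak(cg, noise_floor(cg)).significant
            cgs.append(cg)
        _, _, ga_peak, _ = grand_average(cgs)
        assert ga_peak.significant
        assert ga_peak.delay_ms == pytest.approx(1.0, abs=0.5)


class TestDetectionRate:
    def _peak(self, sig):
        return DPOAEPeak(1.0, 1.0, sig, "trial_p97", (-2, 4))

    def test_rates(self):
        peaks = [self._peak(True)] * 7 + [self._peak(False)] * 13
        rates = detection_rate(peaks, ["g"] * 20)
        assert rates["g"] == pytest.approx(35.0)
        rates_all = detection_rate([self._peak(True)] * 5, ["a"] * 5)
        assert rates_all["a"] == pytest.approx(100.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            detection_rate([], [])


class TestHardwareDelay:
    @pytest.mark.parametrize("hw_ms", [0.0, 1.7, 3.2])
    def test_delay_recovered_and_corrected(self, small_stimulus, hw_ms):
        wdp = small_stimulus.pairs[0].w_dp
        noise = white_noise_rms_for_inband_snr(wdp, small_stimulus.fs, 20.0, gain=1e-3)
        rec = simulate_recording(small_stimulus,
                                 [EmissionSpec(0, gain=1e-3, delay_ms=1.0)],
                                 noise_rms=noise, leak_gain=1.0,
                                 hardware_delay_ms=hw_ms, seed=8)
        est = estimate_hardware_delay(rec, small_stimulus)
        assert est == pytest.approx(hw_ms, abs=0.1)
        cg = complex_xcorr(correct_delay(rec, est), wdp)
        peak = detect_trial_peak(cg, noise_floor(cg))
        assert peak.delay_ms == pytest.approx(1.0, abs=0.25)

    def test_pure_noise_has_no_lock(self, tiny_stimulus, rng):
        rec = EarCanalRecording(samples=1e-3 * rng.standard_normal(2 * FS), fs=FS)
        with pytest.raises(NoStimulusLockError):
            estimate_hardware_delay(rec, tiny_stimulus)


class TestCorrelationWidth:
    def test_crosscorrelation_width_parallels_autocorrelation(self, small_stimulus):
        """Emission peaks are as wide as the template autocorrelation; the
        temporal resolution is set by the waveform, not by jitter."""
        wdp = small_stimulus.pairs[0].w_dp

        def fwhm(cg):
            env = cg.envelope
            i = np.argmax(env)
            half = env[i] / 2
            left = i
            while left > 0 and env[left] > half:
                left -= 1
            right = i
            while right < env.size - 1 and env[right] > half:
                right += 1
            return cg.lags_ms[right] - cg.lags_ms[left]

        auto = complex_xcorr(EarCanalRecording(samples=wdp, fs=FS), wdp)
        noise = white_noise_rms_for_inband_snr(wdp, FS, 30.0, gain=1e-3)
        rec = simulate_recording(small_stimulus,
                                 [EmissionSpec(0, gain=1e-3, delay_ms=1.0)],
                                 noise_rms=noise, seed=3)
        cross = complex_xcorr(rec, wdp)
        assert fwhm(cross) == pytest.approx(fwhm(auto), rel=0.2)
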