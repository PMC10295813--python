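import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import periodogram

import breathtrack as bt
from breathtrack.exceptions import DegenerateSignalError, InvalidArgumentError


def _trace(samples, rate=500.0):
    return bt.RespirationTrace(np.asarray(samples, float), rate)


class TestSmoothAndCenter:
    def test_constant_maps_to_zero(self):
        out = bt.smooth_and_center(_trace(np.full(5000, 7.3)))
        assert np.allclose(out.samples, 0.0, atol=1e-9)

    def test_passband_sinusoid_preserved_without_phase_shift(self, sine_trace):
        out = bt.smooth_and_center(sine_trace)
        r = np.corrcoef(out.samples, sine_trace.samples)[0, 1]
        assert r >= 0.999
        # zero phase: every detected peak stays put
        from scipy.signal import find_peaks

        p_in, _ = find_peaks(sine_trace.samples, distance=1000)
        p_out, _ = find_peaks(out.samples, distance=1000)
        assert len(p_in) == len(p_out)
        assert np.max(np.abs(p_in - p_out)) <= 1

    def test_high_frequency_component_attenuated(self):
        rate, dur = 500.0, 60.0
        t = np.arange(int(dur * rate)) / rate
        x = np.sin(2 * np.pi * 0.2 * t) + 0.5 * np.sin(2 * np.pi * 10.0 * t)
        out = bt.smooth_and_center(_trace(x))
        # periodogram oracle: residual 10 Hz amplitude < 10% of input amplitude
        f, pxx_in = periodogram(x, fs=rate)
        _, pxx_out = periodogram(out.samples, fs=rate)
        band = (f > 9.5) & (f < 10.5)
        assert np.sqrt(pxx_out[band].sum()) < 0.1 * np.sqrt(pxx_in[band].sum())

    def test_rejects_trace_shorter_than_window(self):
        with pytest.raises(InvalidArgumentError):
            bt.smooth_and_center(_trace(np.random.default_rng(0).normal(size=600)))


class TestZscore:
    def test_normalizes_mean_and_sd(self):
        x = np.random.default_rng(1).normal(5, 3, 10_000)
        out = bt.zscore(_trace(x))
        assert abs(out.samples.mean()) < 1e-12
        assert abs(out.samples.std() - 1) < 1e-12

    def test_idempotent(self):
        x = np.random.default_rng(2).normal(size=5000)
        once = bt.zscore(_trace(x))
        twice = bt.zscore(once)
        assert np.allclose(once.samples, twice.samples)

    @settings(max_examples=25, deadline=None)
    @given(
        a=st.floats(min_value=0.1, max_value=50),
        b=st.floats(min_value=-100, max_value=100),
        seed=st.integers(0, 2**16),
    )
    def test_affine_invariance(self, a, b, seed):
        x = np.random.default_rng(seed).normal(size=2000)
        z1 = bt.zscore(_trace(x)).samples
        z2 = bt.zscore(_trace(a * x + b)).samples
        assert np.allclose(z1, z2, atol=1e-8)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateSignalError):
            bt.zscore(_trace(np.ones(2000)))


class TestDetectExtrema:
    def test_sinusoid_extrema_at_analytic_positions(self):
        rate, dur, f = 500.0, 30.0, 0.2
        t = np.arange(int(dur * rate)) / rate
        z = bt.zscore(_trace(np.sin(2 * np.pi * f * t)))
        ext = bt.detect_extrema(z)
        assert ext.n_peaks == 6 and ext.n_troughs == 6
        true_peaks = ((np.arange(6) + 0.25) / f * rate).astype(int)
        assert np.all(np.abs(ext.peak_indices - true_peaks) <= 1)

    def test_small_ripples_rejected_by_prominence_rule(self):
        rate, dur = 500.0, 30.0
        t = np.arange(int(dur * rate)) / rate
        clean = np.sin(2 * np.pi * 0.2 * t)
        rippled = clean + 0.1 * np.sin(2 * np.pi * 0.45 * t)
        e1 = bt.detect_extrema(bt.zscore(_trace(clean)))
        e2 = bt.detect_extrema(bt.zscore(_trace(rippled)))
        assert e1.n_peaks == e2.n_peaks
        assert e1.n_troughs == e2.n_troughs

    def test_extrema_alternate_and_respect_spacing(self):
        prof = bt.BreathingProfile(frequency_drift_sd=0.01)
        trace, _ = bt.generate_respiration(prof, 120.0, 500.0, seed=13)
        z = bt.zscore(bt.smooth_and_center(trace))
        ext = bt.detect_extrema(z)
        merged = np.sort(np.concatenate([ext.peak_indices, ext.trough_indices]))
        kinds = np.isin(merged, ext.peak_indices)
        assert np.all(kinds[1:] != kinds[:-1])  # strict alternation
        fs = z.sampling_rate
        assert np.all(np.diff(ext.peak_indices) >= 2.0 * fs)
        assert np.all(np.diff(ext.trough_indices) >= 2.0 * fs)

    def test_flat_signal_yields_empty_set_with_warning(self):
        with pytest.warns(UserWarning):
            ext = bt.detect_extrema(_trace(np.zeros(5000)))
        assert ext.n_peaks == 0 and ext.n_troughs == 0


class TestFrequencyEstimation:
    @pytest.mark.parametrize("f_true", [0.10, 0.20, 0.30])
    def test_constant_rate_recovered_within_resolution(self, f_true):
        rate, dur = 500.0, 40.0
        t = np.arange(int(dur * rate)) / rate
        est = bt.estimate_frequency_trial(_trace(np.sin(2 * np.pi * f_true * t)))
        assert abs(est.value_hz - f_true) <= 0.01
        assert not est.low_confidence

    def test_dominant_component_wins(self):
        rate, dur = 500.0, 60.0
        t = np.arange(int(dur * rate)) / rate
        x = np.sin(2 * np.pi * 0.2 * t) + 0.3 * np.sin(2 * np.pi * 0.4 * t)
        # periodogram-argmax oracle on the banded spectrum
        f, pxx = periodogram(x, fs=rate, nfft=2**18)
        band = (f >= 0.05) & (f <= 1.0)
        oracle = f[band][np.argmax(pxx[band])]
        est = bt.estimate_frequency_trial(_trace(x))
        assert abs(est.value_hz - oracle) <= 0.01
        assert abs(est.value_hz - 0.2) <= 0.01

    def test_white_noise_flagged_low_confidence(self):
        x = np.random.default_rng(3).normal(size=30_000)
        est = bt.estimate_frequency_trial(_trace(x))
        assert 0.05 <= est.value_hz <= 1.0
        assert est.low_confidence

    def test_short_segment_rejected(self):
        with pytest.raises(InvalidArgumentError):
            bt.estimate_frequency_trial(_trace(np.random.default_rng(0).normal(size=2000)))

    def test_sliding_series_matches_volume_grid(self, sine_trace):
        fs = bt.estimate_frequency_sliding(sine_trace, tr_s=2.0)
        assert len(fs.values) == 30  # 60 s / TR 2 s
        assert np.all(np.abs(fs.values - 0.2) <= 0.01)

    def test_sliding_tracks_frequency_step_within_one_window(self):
        rate = 500.0
        t1 = np.arange(int(60 * rate)) / rate
        x = np.concatenate(
            [np.sin(2 * np.pi * 0.15 * t1), np.sin(2 * np.pi * 0.30 * t1)]
        )
        fs = bt.estimate_frequency_sliding(_trace(x), window_s=10.0, tr_s=2.0)
        before = fs.values[fs.grid < 55]
        after = fs.values[fs.grid > 65]
        assert np.all(np.abs(before - 0.15) <= 0.02)
        assert np.all(np.abs(after - 0.30) <= 0.02)

    def test_sliding_and_trial_estimates_agree_for_stationary_signal(self, sine_trace):
        trial = bt.estimate_frequency_trial(sine_trace)
        sliding = bt.estimate_frequency_sliding(sine_trace, tr_s=2.0)
        assert abs(np.mean(sliding.values) - trial.value_hz) <= 0.01


class TestRVT:
    def test_constant_amplitude_sinusoid_rvt_is_flat(self, sine_trace):
        z = bt.zscore(sine_trace)
        ext = bt.detect_extrema(z)
        rvt = bt.compute_rvt(z, ext)
        interior = rvt.values[ext.all_indices()[0] : ext.all_indices()[-1]]
        assert np.allclose(interior, 2 * np.sqrt(2), rtol=0.02)

    def test_envelopes_pass_through_their_extrema(self, sine_trace):
        z = bt.zscore(sine_trace)
        ext = bt.detect_extrema(z)
        rvt = bt.compute_rvt(z, ext)
        assert np.allclose(rvt.upper_envelope[ext.peak_indices], z.samples[ext.peak_indices])
        assert np.allclose(rvt.lower_envelope[ext.trough_indices], z.samples[ext.trough_indices])

    def test_amplitude_ramp_tracked_at_midpoint(self):
        rate, dur, f = 500.0, 120.0, 0.2
        t = np.arange(int(dur * rate)) / rate
        amp = 1.0 + t / dur  # 1 -> 2
        x = amp * np.sin(2 * np.pi * f * t)
        z = bt.zscore(_trace(x))
        ext = bt.detect_extrema(z)
        rvt = bt.compute_rvt(z, ext)
        sigma = x.std()
        expected_mid = 2 * 1.5 / sigma  # envelope difference at the run midpoint, z-units
        mid = int(len(t) / 2)
        assert abs(rvt.values[mid] - expected_mid) / expected_mid < 0.05

    def test_rvt_nonnegative_on_noisy_breathing(self):
        trace, _ = bt.generate_respiration(bt.BreathingProfile(), 120.0, 500.0, seed=21)
        z = bt.zscore(bt.smooth_and_center(trace))
        rvt = bt.compute_rvt(z, bt.detect_extrema(z))
        assert np.all(rvt.values >= 0)

    def test_insufficient_extrema_rejected(self):
        z = bt.zscore(_trace(np.sin(2 * np.pi * 0.2 * np.arange(3000) / 500.0)))
        with pytest.warns(UserWarning):
            ext = bt.detect_extrema(_trace(np.zeros(3000)))
        with pytest.raises(DegenerateSignalError):
            bt.compute_rvt(z, ext)
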