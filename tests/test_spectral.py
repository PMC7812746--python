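"""Wavelet decomposition, power spectra, coherence and phase estimators."""

import numpy as np
import pytest
from scipy import signal as sps

from cerecoh.containers import TrialTensor
from cerecoh.spectral import (
    event_coherence,
    phase_difference,
    power_spectrum,
    remove_line_noise,
    trial_coherence,
    wavelet_transform,
)
from cerecoh.synthetic import ar2_coefficients, ar2_power_spectrum


class TestWaveletTransform:
    def test_sinusoid_amplitude_at_matching_frequency(self, sine_tensor):
        freqs = np.array([20.0, 30.0, 40.0, 55.0, 80.0])
        tf = wavelet_transform(sine_tensor, freqs)
        mid = np.abs(tf.coeffs[0, 0, :, 400:600]).mean(axis=1)
        assert freqs[np.argmax(mid)] == 40.0
        assert mid[2] == pytest.approx(1.0, abs=0.05)

    def test_zero_signal_zero_coefficients(self):
        trials = TrialTensor(np.zeros((2, 1, 500)), 500.0, (0.5, 0.5))
        tf = wavelet_transform(trials, np.array([10.0, 40.0]))
        assert np.abs(tf.coeffs).max() == 0.0

    def test_linearity_in_amplitude(self, sine_tensor):
        freqs = np.array([10.0, 40.0])
        tf1 = wavelet_transform(sine_tensor, freqs, dtype=np.complex128)
        doubled = TrialTensor(
            2 * sine_tensor.data, sine_tensor.sampling_rate, sine_tensor.window
        )
        tf2 = wavelet_transform(doubled, freqs, dtype=np.complex128)
        np.testing.assert_allclose(tf2.coeffs, 2 * tf1.coeffs, rtol=1e-10)

    def test_frequency_above_nyquist_rejected(self, sine_tensor):
        with pytest.raises(ValueError, match="Nyquist"):
            wavelet_transform(sine_tensor, np.array([40.0, 300.0]))

    def test_too_few_cycles_rejected(self, sine_tensor):
        with pytest.raises(ValueError, match="cycles"):
            wavelet_transform(sine_tensor, np.array([40.0]), cycles=1.0)


class TestPowerSpectrum:
    def test_white_noise_parseval(self, rng):
        x = rng.standard_normal(200_000)
        f, p = power_spectrum(x, 500.0, segment_length=2048)
        assert np.trapezoid(p, f) == pytest.approx(x.var(), rel=0.05)

    def test_sinusoid_peak_location(self):
        fs = 500.0
        t = np.arange(50_000) / fs
        f, p = power_spectrum(np.sin(2 * np.pi * 73.0 * t), fs, segment_length=4096)
        assert abs(f[np.argmax(p)] - 73.0) < fs / 4096 + 1e-9

    def test_ar2_matches_analytic_spectrum(self, rng):
        fs, f0, bw = 500.0, 40.0, 10.0
        a1, a2 = ar2_coefficients(f0, bw, fs)
        e = rng.standard_normal(400_000)
        x = sps.lfilter([1.0], [1.0, -a1, -a2], e)[2000:]
        x /= x.std()
        f, p = power_spectrum(x, fs, segment_length=4096)
        p_true = ar2_power_spectrum(f, f0, bw, fs)
        sel = (f > 20) & (f < 80)
        np.testing.assert_allclose(p[sel], p_true[sel], rtol=0.25)

    def test_segment_longer_than_signal_rejected(self):
        with pytest.raises(ValueError, match="segment"):
            power_spectrum(np.zeros(100), 500.0, segment_length=200)


class TestCoherence:
    def test_self_coherence_is_one(self, coupled_trials):
        coh = trial_coherence(coupled_trials, 0, 0, freqs=np.array([10.0, 40.0]))
        np.testing.assert_allclose(coh.coherence, 1.0, atol=1e-6)

    def test_identical_trials_give_unit_coherence_any_k(self, rng):
        x = rng.standard_normal(400)
        for k in (2, 5, 20):
            data = np.tile(x, (k, 2, 1))
            trials = TrialTensor(data, 500.0, (0.2, 0.6))
            coh = trial_coherence(trials, 0, 1, freqs=np.array([15.0, 40.0]), mode="full")
            np.testing.assert_allclose(coh.coherence, 1.0, atol=1e-6)
            assert coh.n_trials == k

    def test_rescaling_invariance(self, coupled_trials):
        freqs = np.array([20.0, 40.0])
        c1 = trial_coherence(coupled_trials, 0, 2, freqs=freqs, mode="full")
        scaled = TrialTensor(
            coupled_trials.data * np.array([5.0, 1, 0.1, 1])[None, :, None],
            coupled_trials.sampling_rate,
            coupled_trials.window,
        )
        c2 = trial_coherence(scaled, 0, 2, freqs=freqs, mode="full")
        np.testing.assert_allclose(c1.coherence, c2.coherence, rtol=1e-5)

    def test_coherence_bounded(self, coupled_trials):
        coh = trial_coherence(coupled_trials, 0, 2, freqs=np.geomspace(4, 100, 10))
        assert np.all(coh.coherence >= 0.0) and np.all(coh.coherence <= 1.0)

    def test_common_signal_construction_gives_half(self, coupled_trials, coupled_spec):
        # X = sqrt(.5) S + sqrt(.5) N1, Y = sqrt(.5) S + sqrt(.5) N2
        freqs = np.array([38.0, 40.0, 42.0])
        coh = trial_coherence(coupled_trials, 0, 2, freqs=freqs, mode="full")
        assert np.abs(coh.coherence - 0.5).max() < 0.07

    def test_streaming_matches_event_coherence(self, coupled_trials):
        freqs = np.geomspace(8, 80, 6)
        sub = TrialTensor(
            coupled_trials.data[:20],
            coupled_trials.sampling_rate,
            coupled_trials.window,
            coupled_trials.conditions[:20],
        )
        tf = wavelet_transform(sub, freqs, dtype=np.complex128)
        ref = event_coherence(tf.channel(0), tf.channel(2), mode="full")
        stream = trial_coherence(sub, 0, 2, freqs=freqs, mode="full", batch=7)
        np.testing.assert_allclose(ref.coherence, stream.coherence, atol=1e-4)

    def test_single_trial_rejected(self):
        trials = TrialTensor(np.zeros((1, 2, 300)), 500.0, (0.2, 0.4))
        with pytest.raises(ValueError, match="2 trials"):
            trial_coherence(trials, 0, 1, freqs=np.array([20.0]))

    def test_mismatched_grids_rejected(self, coupled_trials):
        sub = TrialTensor(
            coupled_trials.data[:5],
            coupled_trials.sampling_rate,
            coupled_trials.window,
        )
        tf1 = wavelet_transform(sub, np.array([10.0, 20.0]))
        tf2 = wavelet_transform(sub, np.array([10.0, 25.0]))
        with pytest.raises(ValueError, match="grids"):
            event_coherence(tf1.channel(0), tf2.channel(1))


class TestLineNoise:
    @staticmethod
    def contaminated_spectrum(amp=2.0, rng=None):
        rng = rng or np.random.default_rng(5)
        fs = 500.0
        t = np.arange(100_000) / fs
        x = rng.standard_normal(len(t)) + amp * np.sin(2 * np.pi * 50.0 * t)
        return power_spectrum(x, fs, segment_length=2048)

    def test_line_peak_flattened(self):
        f, p = self.contaminated_spectrum()
        f2, p2 = remove_line_noise((f, p), 50.0)
        flank = p2[((f2 >= 45) & (f2 <= 48)) | ((f2 >= 52) & (f2 <= 55))].mean()
        assert p2[np.argmin(np.abs(f2 - 50.0))] / flank <= 1.5

    def test_noop_on_clean_spectrum(self):
        f, p = self.contaminated_spectrum(amp=0.0)
        _, p2 = remove_line_noise((f, p), 50.0)
        assert np.abs(p2 - p).max() / p.max() < 0.01

    def test_idempotence(self):
        f, p = self.contaminated_spectrum()
        _, p1 = remove_line_noise((f, p), 50.0)
        _, p2 = remove_line_noise((f, p1), 50.0)
        np.testing.assert_allclose(p1, p2, rtol=1e-6)

    def test_edge_frequency_rejected(self):
        f = np.linspace(0, 52, 100)
        with pytest.raises(ValueError, match="edge"):
            remove_line_noise((f, np.ones_like(f)), 50.0)

    def test_tf_phases_untouched(self, coupled_trials):
        freqs = np.linspace(40, 60, 11)
        sub = TrialTensor(
            coupled_trials.data[:5], coupled_trials.sampling_rate, coupled_trials.window
        )
        tf = wavelet_transform(sub, freqs, dtype=np.complex128)
        cleaned = remove_line_noise(tf, 50.0, half_width=2.0, flank_width=6.0)
        np.testing.assert_allclose(
            np.angle(cleaned.coeffs[np.abs(cleaned.coeffs) > 1e-9]),
            np.angle(tf.coeffs[np.abs(tf.coeffs) > 1e-9]),
            atol=1e-6,
        )


class TestPhaseDifference:
    @staticmethod
    def delayed_pair(delay_s=0.005, fs=500.0, k=40, rng=None):
        rng = rng or np.random.default_rng(8)
        lag = int(round(delay_s * fs))
        n = 1000
        data = np.empty((k, 2, n))
        for i in range(k):
            x = rng.standard_normal(n + lag)
            x = sps.lfilter(*sps.butter(2, [0.05, 0.45], btype="band"), x)
            data[i, 0] = x[lag:]
            data[i, 1] = x[: n] if lag else x
        return TrialTensor(data, fs, (0.5, 1.0))

    def test_pure_delay_gives_linear_phase_slope(self):
        tau = 0.006  # exactly 3 samples at 500 Hz
        trials = self.delayed_pair(tau)
        freqs = np.linspace(20, 60, 9)
        tf = wavelet_transform(trials, freqs, dtype=np.complex128)
        res = phase_difference(tf.channel(0), tf.channel(1), mode="full")
        implied = np.unwrap(res.dphi) / (2 * np.pi * freqs)
        assert np.abs(implied - tau).max() < 0.001

    def test_identical_signals_zero_phase(self, coupled_trials):
        freqs = np.array([10.0, 40.0])
        sub = TrialTensor(
            coupled_trials.data[:10, [0, 0], :],
            coupled_trials.sampling_rate,
            coupled_trials.window,
        )
        tf = wavelet_transform(sub, freqs, dtype=np.complex128)
        res = phase_difference(tf.channel(0), tf.channel(1), mode="full")
        np.testing.assert_allclose(res.dphi, 0.0, atol=1e-6)

    def test_argument_swap_flips_sign(self):
        trials = self.delayed_pair(0.004)
        freqs = np.linspace(20, 60, 5)
        tf = wavelet_transform(trials, freqs, dtype=np.complex128)
        fwd = phase_difference(tf.channel(0), tf.channel(1), mode="full")
        rev = phase_difference(tf.channel(1), tf.channel(0), mode="full")
        np.testing.assert_allclose(fwd.dphi, -rev.dphi, atol=1e-9)

    def test_weak_cross_spectrum_flagged(self, rng):
        data = rng.standard_normal((30, 2, 800))
        trials = TrialTensor(data, 500.0, (0.5, 1.1))
        tf = wavelet_transform(trials, np.array([20.0, 40.0]))
        res = phase_difference(tf.channel(0), tf.channel(1), mode="full",
                               reliability_floor=0.3)
        assert res.unreliable.all()
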