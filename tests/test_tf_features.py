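import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.signal import get_window

from respvit import tf_features as tf
from respvit.errors import ParameterError


def brute_stft_frame(x, w, N):
    """Direct-summation DFT of one windowed frame (independent oracle)."""
    k = np.arange(N // 2 + 1)
    n = np.arange(N)
    D = np.exp(-2j * np.pi * np.outer(k, n) / N)
    return np.abs(D @ (x[:N] * w))


class TestSTFT:
    def test_zero_signal_gives_zero_matrix(self):
        rep = tf.stft(np.zeros(1000), tf.STFTParams("hann", 256, 128), 4000.0)
        assert rep.values.shape == (129, 1 + (1000 - 256) // 128)
        assert np.all(rep.values == 0)

    def test_impulse_has_flat_spectrum(self):
        x = np.zeros(300)
        x[0] = 1.0
        rep = tf.stft(x, tf.STFTParams("boxcar", 256, 128), 4000.0)
        np.testing.assert_allclose(rep.values[:, 0], 1.0, atol=1e-12)

    def test_quarter_rate_sine_peaks_at_bin_64(self):
        fs, N = 4000.0, 256
        t = np.arange(4000) / fs
        x = np.sin(2 * np.pi * (fs / 4) * t)
        rep = tf.stft(x, tf.STFTParams("boxcar", N, N), fs)
        assert np.argmax(rep.values[:, 0]) == 64
        assert rep.values[64, 0] == pytest.approx(N / 2, rel=1e-9)

    def test_matches_direct_dft_on_random_signals(self, rng):
        for _ in range(10):
            n = int(rng.integers(300, 1024))
            N = int(rng.choice([64, 128, 256]))
            J = N // 2
            x = rng.standard_normal(n)
            w = get_window("hann", N, fftbins=True)
            rep = tf.stft(x, tf.STFTParams("hann", N, J), 4000.0)
            m = int(rng.integers(0, rep.values.shape[1]))
            oracle = brute_stft_frame(x[m * J:], w, N)
            assert np.max(np.abs(rep.values[:, m] - oracle)) < 1e-8

    def test_signal_shorter_than_frame_rejected(self):
        with pytest.raises(ParameterError):
            tf.stft(np.zeros(100), tf.STFTParams("hann", 256, 128), 4000.0)


class TestMel:
    def test_scale_closed_forms(self):
        assert tf.mel_scale(0.0) == 0.0
        assert tf.mel_scale(700.0) == pytest.approx(1127 * np.log(2), rel=1e-12)
        assert tf.mel_scale(1000.0) == pytest.approx(999.99, abs=0.05)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ParameterError):
            tf.mel_scale(-1.0)

    def test_mel_inverse_round_trip(self):
        f = np.linspace(0, 2000, 50)
        np.testing.assert_allclose(tf.mel_to_hz(tf.mel_scale(f)), f, atol=1e-9)

    def test_centres_equispaced_on_mel_scale(self):
        p = tf.MelParams(M=12, fmin=0, fmax=2000)
        mels = tf.mel_scale(tf.mel_centre_frequencies(p))
        np.testing.assert_allclose(np.diff(mels), np.diff(mels)[0], rtol=1e-9)

    def test_three_filter_middle_centre(self):
        # middle peak sits where the Mel value is half of Mel(2000)
        p = tf.MelParams(M=3, fmin=0, fmax=2000)
        centres = tf.mel_centre_frequencies(p)
        target = 700.0 * (np.exp(tf.mel_scale(2000.0) / 2.0 / 1127.0) - 1.0)
        assert centres[1] == pytest.approx(target, rel=1e-9)

    def test_filterbank_support_and_peaks(self):
        fs, n_fft = 4000.0, 512
        p = tf.MelParams(M=10, fmin=100, fmax=1800)
        H = tf.mel_filterbank(fs, n_fft, p)
        assert H.shape == (10, 257)
        bin_freqs = np.arange(257) * fs / n_fft
        outside = (bin_freqs < 100) | (bin_freqs > 1800)
        assert np.all(H[:, outside] == 0)
        assert np.all(H >= 0)
        # each filter peaks at the bin nearest its design centre
        centres = tf.mel_centre_frequencies(p)
        for m in range(10):
            peak_bin = np.argmax(H[m])
            assert abs(bin_freqs[peak_bin] - centres[m]) <= fs / n_fft

    def test_bandwidths_increase_with_frequency(self):
        H = tf.mel_filterbank(4000.0, 512, tf.MelParams(M=8, fmin=0, fmax=2000))
        widths = (H > 0).sum(axis=1)
        assert widths[-1] > widths[0]

    def test_too_many_filters_collide(self):
        with pytest.raises(ParameterError):
            tf.mel_filterbank(4000.0, 64, tf.MelParams(M=40, fmin=0, fmax=2000))


class TestMFCC:
    def test_dct_of_constant_is_dc_only(self):
        M = 8
        C = tf._dct_matrix(M, M)
        y = C @ np.full(M, 3.0)
        assert y[0] == pytest.approx(np.sqrt(2.0 / M) * M * 3.0)
        np.testing.assert_allclose(y[1:], 0.0, atol=1e-12)

    def test_dct_of_unit_vector_hand_values(self):
        # S = (1, 0, 0, 0), M = 4 -> Y_n = sqrt(1/2) cos(pi n / 8)
        C = tf._dct_matrix(4, 4)
        y = C @ np.array([1.0, 0.0, 0.0, 0.0])
        expect = np.sqrt(0.5) * np.cos(np.pi * np.arange(4) / 8.0)
        np.testing.assert_allclose(y, expect, rtol=1e-12)

    def test_frame_count_matches_stft(self, rng):
        x = rng.standard_normal(4000)
        sp = tf.STFTParams("hann", 256, 128)
        mp = tf.MelParams(M=20, fmin=0, fmax=2000, n_mfcc=12)
        rep = tf.mfcc(x, sp, mp, 4000.0)
        assert rep.values.shape == (12, tf.stft(x, sp, 4000.0).values.shape[1])
        assert rep.scale == "cepstral"

    def test_silent_frames_hit_log_floor_not_error(self):
        sp = tf.STFTParams("hann", 256, 128)
        mp = tf.MelParams(M=16, fmin=0, fmax=2000, n_mfcc=8)
        rep = tf.mfcc(np.zeros(2000), sp, mp, 4000.0)
        assert np.all(np.isfinite(rep.values))


class TestCQT:
    def test_octave_doubles_frequency(self):
        freqs = tf.cqt_frequencies(tf.CQTParams(f1=100, b=12, fmax=2000))
        assert freqs[12] == pytest.approx(200.0, rel=1e-12)
        np.testing.assert_allclose(freqs[12:] / freqs[:-12], 2.0, rtol=1e-12)

    def test_q_factor_constant(self):
        freqs = tf.cqt_frequencies(tf.CQTParams(f1=100, b=12, fmax=2000))
        delta = freqs * (2.0 ** (1.0 / 12) - 1.0)
        Q = freqs / delta
        np.testing.assert_allclose(Q, Q[0], rtol=1e-9)

    def test_pure_tone_peaks_at_nearest_bin(self, rng):
        fs = 4000.0
        t = np.arange(int(2 * fs)) / fs
        x = np.sin(2 * np.pi * 400.0 * t)
        p = tf.CQTParams(f1=100, b=12, fmax=2000)
        rep = tf.cqt(x, p, fs)
        expected_bin = np.argmin(np.abs(rep.freqs - 400.0))
        mid = rep.values.shape[1] // 2
        assert np.argmax(rep.values[:, mid]) == expected_bin

    def test_direct_summation_oracle(self, rng):
        # independently evaluate the atom correlation for a few (bin, frame) cells
        fs = 4000.0
        x = rng.standard_normal(3000)
        p = tf.CQTParams(f1=200, b=6, fmax=1600, hop_s=0.1)
        rep = tf.cqt(x, p, fs)
        Q = 1.0 / (2.0 ** (1.0 / p.b) - 1.0)
        hop = round(p.hop_s * fs)
        for ki in (0, 3, rep.freqs.size - 1):
            fk = p.f1 * 2.0 ** (ki / p.b)
            nk = int(np.ceil(Q * fs / fk))
            w = get_window("hann", nk, fftbins=True)
            ci = 5
            c = ci * hop
            acc = 0.0 + 0.0j
            for n in range(nk):
                j = c - nk // 2 + n
                if 0 <= j < x.size:
                    acc += x[j] * (w[n] / nk) * np.exp(-2j * np.pi * n * fk / fs)
            assert abs(rep.values[ki, ci] - abs(acc)) < 1e-10

    def test_atom_longer_than_signal_rejected(self):
        with pytest.raises(ParameterError):
            tf.cqt(np.zeros(100), tf.CQTParams(f1=100, b=12, fmax=2000), 4000.0)


class TestGammatone:
    def test_erb_closed_forms(self):
        assert tf.erb(0.0) == pytest.approx(24.7)
        assert tf.erb(1000.0) == pytest.approx(24.7 * 5.37, rel=1e-12)
        assert tf.gammatone_bandwidth(1000.0) == pytest.approx(1.019 * 24.7 * 5.37, rel=1e-12)

    def test_bank_endpoints_and_monotonicity(self):
        bank = tf.design_gammatone_bank(4000.0, K=64, fmin=100.0)
        assert bank.fc[0] == pytest.approx(100.0, abs=1e-6)
        assert bank.fc[-1] == pytest.approx(2000.0, abs=1e-6)
        assert np.all(np.diff(bank.fc) > 0)
        assert bank.K == 64 and bank.order == 4

    def test_three_channel_midpoint_on_erb_rate_integral(self):
        # invert the ERB-rate integral numerically, independent of the package
        bank = tf.design_gammatone_bank(4000.0, K=3, fmin=100.0, fmax=2000.0)

        def rate(f):
            return quad(lambda g: 1.0 / (24.7 * (4.37 * g / 1000.0 + 1.0)), 0, f)[0]

        mid_rate = 0.5 * (rate(100.0) + rate(2000.0))
        f_mid = brentq(lambda f: rate(f) - mid_rate, 100.0, 2000.0)
        assert bank.fc[1] == pytest.approx(f_mid, rel=1e-6)

    def test_linear_spacing_flag(self):
        bank = tf.design_gammatone_bank(4000.0, K=5, fmin=100.0, fmax=2000.0, spacing="linear")
        np.testing.assert_allclose(np.diff(bank.fc), 475.0)

    def test_ir_zero_at_origin_for_order_four(self):
        g = tf.gammatone_ir(500.0, 4, tf.gammatone_bandwidth(500.0), 4000.0)
        assert g[0] == 0.0
        assert np.max(np.abs(g)) == pytest.approx(1.0)

    def test_envelope_peak_time(self):
        fc, o = 500.0, 4
        b = tf.gammatone_bandwidth(fc)
        fs = 200000.0  # fine grid so the sampled argmax resolves the analytic peak
        t = np.arange(int(0.05 * fs)) / fs
        env = t ** (o - 1) * np.exp(-2 * np.pi * b * t)
        t_peak = (o - 1) / (2 * np.pi * b)
        assert abs(t[np.argmax(env)] - t_peak) < 2.0 / fs

    def test_envelope_decays_below_one_percent(self):
        fc, o = 500.0, 4
        b = tf.gammatone_bandwidth(fc)
        t_peak = (o - 1) / (2 * np.pi * b)
        t = np.linspace(10 * t_peak, 20 * t_peak, 500)
        env = t ** (o - 1) * np.exp(-2 * np.pi * b * t)
        peak = t_peak ** (o - 1) * np.exp(-(o - 1))
        assert np.all(env < 0.01 * peak)

    def test_ir_absolutely_summable_truncation(self):
        b = tf.gammatone_bandwidth(100.0)
        g = tf.gammatone_ir(100.0, 4, b, 4000.0)
        assert np.isfinite(np.abs(g).sum())
        assert np.abs(g[-1]) < 0.01  # truncated in the decayed tail


class TestCochleogram:
    def test_silence_maps_to_zero(self):
        bank = tf.design_gammatone_bank(4000.0, K=16)
        rep = tf.cochleogram(np.zeros(4000), bank)
        assert np.all(rep.values == 0)

    def test_tone_peaks_in_nearest_channel(self):
        fs = 4000.0
        bank = tf.design_gammatone_bank(fs, K=64)
        t = np.arange(int(2 * fs)) / fs
        rep = tf.cochleogram(np.sin(2 * np.pi * 500.0 * t), bank)
        target = np.argmin(np.abs(bank.fc - 500.0))
        for m in range(rep.values.shape[1]):
            assert abs(int(np.argmax(rep.values[:, m])) - target) <= 1

    def test_energy_is_quadratic_in_amplitude(self, rng):
        fs = 4000.0
        bank = tf.design_gammatone_bank(fs, K=8)
        x = rng.standard_normal(2000)
        r1 = tf.cochleogram(x, bank)
        r2 = tf.cochleogram(2 * x, bank)
        np.testing.assert_allclose(r2.values, 4 * r1.values, rtol=1e-9)

    def test_nonnegative_everywhere(self, rng):
        bank = tf.design_gammatone_bank(4000.0, K=8)
        rep = tf.cochleogram(rng.standard_normal(2000), bank)
        assert np.all(rep.values >= 0)

    def test_frame_shorter_than_signal_required(self):
        bank = tf.design_gammatone_bank(4000.0, K=4)
        with pytest.raises(ParameterError):
            tf.cochleogram(np.zeros(100), bank, frame_len=0.084)


class TestToImage:
    def test_constant_matrix_is_uniform(self):
        rep = tf.TFRepresentation(np.full((5, 7), 2.0), np.arange(5), np.arange(7.0), "linear")
        img = tf.to_image(rep, 16, 16)
        assert np.unique(img.pixels.reshape(-1, 3), axis=0).shape[0] == 1

    def test_output_shape_independent_of_input_shape(self, rng):
        for K, L in [(3, 50), (64, 10), (129, 129)]:
            rep = tf.TFRepresentation(rng.random((K, L)), np.arange(K), np.arange(L) * 0.1, "linear")
            assert tf.to_image(rep, 224, 100).pixels.shape == (224, 100, 3)

    def test_maximum_maps_to_viridis_endpoint(self, rng):
        rep = tf.TFRepresentation(rng.random((64, 64)) + 0.5, np.arange(64), np.arange(64.0), "linear")
        img = tf.to_image(rep, 64, 64)
        assert np.any(np.all(img.pixels == (253, 231, 37), axis=-1))

    def test_invariant_to_positive_rescaling(self, rng):
        V = rng.random((32, 40)) + 0.1
        rep1 = tf.TFRepresentation(V, np.arange(32), np.arange(40.0), "linear")
        rep2 = tf.TFRepresentation(37.5 * V, np.arange(32), np.arange(40.0), "linear")
        np.testing.assert_array_equal(
            tf.to_image(rep1, 48, 48).pixels, tf.to_image(rep2, 48, 48).pixels
        )

    def test_all_zero_matrix_uses_lowest_colour(self):
        rep = tf.TFRepresentation(np.zeros((4, 4)), np.arange(4), np.arange(4.0), "linear")
        img = tf.to_image(rep, 8, 8)
        assert np.all(img.pixels == np.array([68, 1, 84], dtype=np.uint8))

    def test_low_frequencies_at_bottom(self):
        V = np.zeros((4, 4))
        V[0, :] = 1.0  # energy only in the lowest-frequency row
        rep = tf.TFRepresentation(V, np.arange(4), np.arange(4.0), "linear")
        img = tf.to_image(rep, 4, 4)
        # bottom row should carry the bright endpoint colour
        assert np.all(img.pixels[-1] == np.array([253, 231, 37], dtype=np.uint8))


def test_all_frontends_agree_on_time_span(rng):
    """The four representations of one 6 s cycle span the same time axis
    to within one hop."""
    from respvit import pipeline as pl

    fs = 4000.0
    x = rng.standard_normal(int(6 * fs)) * 0.1
    spans = {}
    for fe in ("stft", "mfcc", "cqt", "cochleogram"):
        rep = pl.compute_tf(x, fs, fe)
        spans[fe] = (rep.frame_times[0], rep.frame_times[-1])
    starts = [s for s, _ in spans.values()]
    ends = [e for _, e in spans.values()]
    hop = 0.042
    assert max(starts) - min(starts) <= hop + 1e-9
    assert max(ends) - min(ends) <= hop + 1e-9
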