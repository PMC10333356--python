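import numpy as np
import pytest

from pamloc.signals import (
    SignalError,
    bandpass,
    call_preset,
    highpass,
    make_chirp,
    make_noise,
    make_tonal_call,
    read_wav,
    write_wav,
)


def lag_of_peak(x, y):
    """Brute-force full cross-correlation peak lag (oracle)."""
    cc = np.correlate(x, y, mode="full")
    return int(np.argmax(cc)) - (len(y) - 1)


class TestChirp:
    def test_sample_count(self):
        assert make_chirp(0.002, 48_000).samples.size == 96

    def test_peak_normalized(self, chirp48k):
        assert np.abs(chirp48k.samples).max() == pytest.approx(1.0)

    def test_autocorrelation_peaks_at_zero_lag(self, chirp48k):
        x = chirp48k.samples
        cc = np.correlate(x, x, mode="full")
        center = len(x) - 1
        assert np.argmax(cc) == center
        assert cc[center] > np.max(np.delete(cc, center))

    def test_cross_correlation_recovers_shift(self, chirp48k):
        x = np.concatenate([chirp48k.samples, np.zeros(32)])
        shifted = np.roll(x, 7)
        assert lag_of_peak(shifted, x) == 7

    def test_too_short_duration_rejected(self):
        with pytest.raises(SignalError):
            make_chirp(1e-6, 48_000)


class TestTonalCall:
    def test_harmonic_stack_peaks(self):
        sr = 48_000
        w = make_tonal_call([(0.0, 2000.0), (1.0, 2000.0)], n_harmonics=3,
                            duration=1.0, sample_rate=sr)
        spec = np.abs(np.fft.rfft(w.samples))
        freqs = np.fft.rfftfreq(w.samples.size, 1 / sr)
        bin_width = freqs[1] - freqs[0]
        for k in (1, 2, 3):
            # strongest line within +-5 bins of each expected harmonic
            window = (freqs > k * 2000 - 200) & (freqs < k * 2000 + 200)
            peak_f = freqs[window][np.argmax(spec[window])]
            assert abs(peak_f - k * 2000) <= bin_width

    def test_zero_duration_rejected(self):
        with pytest.raises(SignalError):
            make_tonal_call([(0, 1000)], 2, 0.0, 48_000)

    def test_aliasing_harmonics_rejected(self):
        with pytest.raises(SignalError):
            make_tonal_call([(0, 9000)], 4, 0.5, 48_000)

    def test_tonal_flatter_than_white_noise(self):
        sr = 48_000
        call = call_preset("N-flat", 0.5, sr)
        noise = make_noise("white", 0.5, sr, seed=3)

        def flatness(x):
            p = np.abs(np.fft.rfft(x)) ** 2 + 1e-30
            return np.exp(np.mean(np.log(p))) / np.mean(p)

        assert flatness(call.samples) < flatness(noise.samples)

    def test_unknown_preset_rejected(self):
        with pytest.raises(SignalError):
            call_preset("N99")


class TestNoise:
    def test_deterministic_for_seed(self):
        a = make_noise("boat", 0.3, 48_000, seed=11)
        b = make_noise("boat", 0.3, 48_000, seed=11)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_white_noise_zero_mean(self):
        w = make_noise("white", 1.0, 48_000, seed=5)
        n = w.samples.size
        sigma = w.samples.std()
        assert abs(w.samples.mean()) < 3 * sigma / np.sqrt(n)

    def test_boat_noise_is_low_frequency_weighted(self):
        w = make_noise("boat", 1.0, 48_000, seed=7)
        p = np.abs(np.fft.rfft(w.samples)) ** 2
        f = np.fft.rfftfreq(w.samples.size, 1 / 48_000)
        assert p[f < 1000].sum() > p[f > 5000].sum()

    def test_unknown_kind_rejected(self):
        with pytest.raises(SignalError):
            make_noise("submarine", 1.0, 48_000)


class TestFilters:
    def tone(self, freq, sr=48_000, duration=0.5):
        t = np.arange(int(duration * sr)) / sr
        from pamloc.signals import Waveform
        return Waveform(np.sin(2 * np.pi * freq * t), sr, "tone")

    def test_stopband_rejection(self):
        w = self.tone(100.0)
        out = bandpass(w, 500.0, 10_000.0)
        ratio = np.sqrt((out.samples**2).mean() / (w.samples**2).mean())
        assert ratio < 0.01

    def test_passband_preserved(self):
        w = self.tone(5000.0)
        out = bandpass(w, 500.0, 10_000.0)
        ratio = np.sqrt((out.samples**2).mean() / (w.samples**2).mean())
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_highpass_strips_interference_band(self):
        w = self.tone(300.0)
        out = highpass(w, 1500.0)
        assert np.sqrt((out.samples**2).mean()) < 0.01

    def test_zero_phase_preserves_interchannel_lag(self, chirp48k):
        from pamloc.signals import Waveform

        pad = np.zeros(400)
        a = np.concatenate([pad, chirp48k.samples, pad])
        b = np.roll(a, 13)
        fa = bandpass(Waveform(a, 48_000), 500, 10_000).samples
        fb = bandpass(Waveform(b, 48_000), 500, 10_000).samples
        # sub-sample lag via parabolic interpolation around the peak
        def sublag(x, y):
            cc = np.correlate(x, y, "full")
            k = np.argmax(cc)
            y0, y1, y2 = cc[k - 1], cc[k], cc[k + 1]
            return k - (len(y) - 1) + 0.5 * (y0 - y2) / (y0 - 2 * y1 + y2)

        assert abs(sublag(fb, fa) - sublag(b, a)) < 0.1

    def test_invalid_band_edges_rejected(self):
        w = self.tone(1000.0)
        with pytest.raises(SignalError):
            bandpass(w, 10_000.0, 500.0)
        with pytest.raises(SignalError):
            highpass(w, 30_000.0)


class TestWavIO:
    @pytest.mark.parametrize("subtype,atol", [("float", 1e-7),
                                              ("pcm16", 1e-4)])
    def test_multichannel_round_trip(self, tmp_path, subtype, atol):
        rng = np.random.default_rng(0)
        data = rng.uniform(-0.9, 0.9, size=(4, 1000))
        path = tmp_path / "x.wav"
        write_wav(path, data, 48_000, subtype=subtype)
        back, rate = read_wav(path)
        assert rate == 48_000
        assert back.shape == data.shape
        np.testing.assert_allclose(back, data, atol=atol)

    def test_rate_mismatch_raises_or_resamples(self, tmp_path):
        path = tmp_path / "y.wav"
        write_wav(path, np.zeros(1000), 44_100)
        with pytest.raises(SignalError):
            read_wav(path, expect_sample_rate=48_000, on_mismatch="error")
        with pytest.warns(UserWarning):
            x, rate = read_wav(path, expect_sample_rate=48_000,
                               on_mismatch="resample")
        assert rate == 48_000
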