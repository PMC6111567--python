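import numpy as np
import pytest

from tfemotion.io_dataset import Segment
from tfemotion.tfr import KernelSpec, analytic_signal, cwd, wvd

FS = 128.0


def seg(values, fs=FS):
    return Segment(values=np.asarray(values, dtype=float), channel="T7", window_index=0, fs=fs)


def tone(freq, n=512, fs=FS, phase=0.0):
    return np.cos(2 * np.pi * freq * np.arange(n) / fs + phase)


def freq_bin(freq, n_bins, fs=FS):
    return int(round(freq / (fs / 2.0) * n_bins))


class TestAnalyticSignal:
    def test_real_part_is_the_input_bitwise(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(256)
        a = analytic_signal(seg(x))
        np.testing.assert_array_equal(a.values.real, x)

    def test_spectrum_is_one_sided(self):
        rng = np.random.default_rng(1)
        a = analytic_signal(seg(rng.standard_normal(512)))
        spectrum = np.fft.fft(a.values)
        negative = spectrum[512 // 2 + 1 :]
        assert np.max(np.abs(negative)) < 1e-9 * np.max(np.abs(spectrum))

    def test_cosine_becomes_unit_complex_exponential(self):
        a = analytic_signal(seg(tone(8.0)))
        interior = slice(32, 480)
        np.testing.assert_allclose(np.abs(a.values[interior]), 1.0, atol=1e-3)
        expected = np.exp(2j * np.pi * 8.0 * np.arange(512) / FS)
        np.testing.assert_allclose(a.values[interior], expected[interior], atol=1e-3)

    def test_sine_imaginary_part_is_minus_cosine(self):
        # frequency-domain Hilbert oracle: HT{sin} = -cos
        t = np.arange(512) / FS
        a = analytic_signal(seg(np.sin(2 * np.pi * 8.0 * t)))
        interior = slice(32, 480)
        np.testing.assert_allclose(
            a.values.imag[interior], -np.cos(2 * np.pi * 8.0 * t)[interior], atol=1e-3
        )

    def test_non_finite_input_is_an_error(self):
        x = np.ones(64)
        x[10] = np.nan
        with pytest.raises(ValueError, match="finite"):
            analytic_signal(seg(x))


class TestWignerVille:
    def test_pure_tone_concentrates_at_its_frequency_bin(self):
        a = analytic_signal(seg(tone(16.0)))
        tfr = wvd(a)
        expected = freq_bin(16.0, tfr.N)
        rows = tfr.values[64:448]
        assert np.all(rows.argmax(axis=1) == expected)

    def test_energy_is_preserved_on_the_grid(self):
        a = analytic_signal(seg(tone(16.0)))
        tfr = wvd(a)
        energy = np.sum(np.abs(a.values) ** 2)
        assert abs(tfr.values.sum() - energy) < 0.05 * energy

    def test_two_tone_cross_term_oscillates_to_zero_mean(self):
        a = analytic_signal(seg(tone(8.0) + tone(24.0)))
        tfr = wvd(a)
        mid = freq_bin(16.0, tfr.N)
        band = tfr.values[64:448, mid - 2 : mid + 3]
        assert np.abs(band).max() > 0.3  # the cross-term is present...
        assert abs(band.mean()) < 0.02 * np.abs(band).max()  # ...but averages out

    def test_chirp_ridge_follows_the_instantaneous_frequency(self):
        import scipy.signal

        t = np.arange(512) / FS
        x = scipy.signal.chirp(t, f0=8.0, f1=40.0, t1=t[-1], method="linear")
        tfr = wvd(analytic_signal(seg(x)))
        inst_freq = 8.0 + (40.0 - 8.0) * t / t[-1]
        expected = np.round(inst_freq / (FS / 2.0) * tfr.N).astype(int)
        rows = np.arange(48, 464)
        deviation = np.abs(tfr.values[rows].argmax(axis=1) - expected[rows])
        assert deviation.max() <= 2

    def test_output_shape_is_m_by_2m(self):
        a = analytic_signal(seg(np.random.default_rng(2).standard_normal(512)))
        assert wvd(a).values.shape == (512, 1024)


class TestChoiWilliams:
    def test_default_grid_is_512_by_1024(self):
        a = analytic_signal(seg(np.random.default_rng(3).standard_normal(512)))
        assert cwd(a).values.shape == (512, 1024)

    def test_large_beta_degenerates_to_wigner_ville(self):
        a = analytic_signal(seg(tone(8.0) + tone(24.0)))
        reference = wvd(a).values
        smoothed = cwd(a, KernelSpec("cwd", beta=1e6)).values
        scale = np.max(np.abs(reference))
        assert np.max(np.abs(smoothed - reference)) < 1e-6 * scale

    def test_cross_terms_suppressed_but_auto_terms_kept(self):
        a = analytic_signal(seg(tone(8.0) + tone(24.0)))
        w = wvd(a)
        c = cwd(a, KernelSpec("cwd", beta=0.5))
        mid = freq_bin(16.0, w.N)
        band = slice(mid - 8, mid + 9)
        assert np.abs(c.values[:, band]).max() < 0.5 * np.abs(w.values[:, band]).max()
        # the auto-term peaks stay put: within each tone's band the ridge
        # position is identical for the smoothed and unsmoothed surfaces
        rows = np.arange(64, 448)
        for f0 in (8.0, 24.0):
            auto = slice(freq_bin(f0, w.N) - 4, freq_bin(f0, w.N) + 5)
            assert np.array_equal(
                c.values[rows, auto].argmax(axis=1), w.values[rows, auto].argmax(axis=1)
            )

    def test_convergence_to_wvd_is_monotone_in_beta(self):
        a = analytic_signal(seg(tone(8.0, n=256) + tone(24.0, n=256)))
        reference = wvd(a).values
        gaps = [
            np.max(np.abs(cwd(a, KernelSpec("cwd", beta=b)).values - reference))
            for b in (0.5, 5.0, 50.0, 500.0)
        ]
        assert gaps == sorted(gaps, reverse=True)

    def test_time_shift_covariance(self):
        # a mid-segment Gaussian tone burst, then the same burst delayed
        n, d = 256, 16
        t = np.arange(n) / FS
        def burst(center):
            return np.exp(-0.5 * ((t - center) / 0.15) ** 2) * np.cos(2 * np.pi * 20 * t)
        x1, x2 = burst(0.8), burst(0.8 + d / FS)
        for transform in (wvd, lambda a: cwd(a, KernelSpec("cwd", 0.5))):
            v1 = transform(analytic_signal(seg(x1))).values
            v2 = transform(analytic_signal(seg(x2))).values
            rows = np.arange(48, n - 48 - d)
            scale = np.max(np.abs(v1))
            assert np.max(np.abs(v2[rows + d] - v1[rows])) < 5e-3 * scale

    def test_invalid_beta_is_an_error(self):
        with pytest.raises(ValueError, match="beta"):
            KernelSpec("cwd", beta=0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_finite_output_for_random_signals(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(96) * 10 ** rng.uniform(-3, 3)
        a = analytic_signal(seg(x))
        assert np.all(np.isfinite(wvd(a).values))
        assert np.all(np.isfinite(cwd(a).values))
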