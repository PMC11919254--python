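"""Masker synthesis and SNR mixing."""

import numpy as np
import pytest
from scipy import signal

from speechtrack.stimuli import (
    ConditionGrid,
    MixtureSpec,
    make_babble,
    mix_at_snr,
    normalize_mixture,
    spectrally_matched_noise,
    synth_noise,
)
from speechtrack.waveform import Waveform

RATE = 8000.0


def unit_rms_noise(n=8000, seed=0):
    x = np.random.default_rng(seed).standard_normal(n)
    return Waveform(x / np.sqrt(np.mean(x**2)), RATE)


class TestMixAtSnr:
    @pytest.mark.parametrize(
        "snr,scale",
        [(20.0, 0.1), (0.0, 1.0), (-2.0, 10.0**0.1)],
    )
    def test_masker_scale_factor(self, snr, scale):
        speech = unit_rms_noise(seed=1)
        masker = unit_rms_noise(seed=2)
        mix = mix_at_snr(speech, masker, snr)
        recovered = mix.samples - speech.samples
        np.testing.assert_allclose(recovered, scale * masker.samples, rtol=1e-9)

    @pytest.mark.parametrize("snr", [-6.0, 0.0, 12.3, 30.0])
    def test_snr_postcondition(self, snr):
        speech = unit_rms_noise(seed=3)
        masker = Waveform(3.7 * unit_rms_noise(seed=4).samples, RATE)
        mix = mix_at_snr(speech, masker, snr)
        scaled = Waveform(mix.samples - speech.samples, RATE)
        assert abs(20 * np.log10(speech.rms() / scaled.rms()) - snr) < 1e-9

    def test_scale_depends_only_on_rms_and_snr(self):
        speech = unit_rms_noise(seed=5)
        m1 = unit_rms_noise(seed=6)
        m2 = Waveform(np.sin(2 * np.pi * 300 * np.arange(8000) / RATE), RATE)
        m2 = Waveform(m2.samples / m2.rms(), RATE)
        s1 = Waveform(mix_at_snr(speech, m1, 10.0).samples - speech.samples, RATE)
        s2 = Waveform(mix_at_snr(speech, m2, 10.0).samples - speech.samples, RATE)
        np.testing.assert_allclose(
            s1.rms() / m1.rms(), s2.rms() / m2.rms(), rtol=1e-9
        )

    def test_longer_masker_cropped_deterministically(self):
        speech = unit_rms_noise(seed=7)
        masker = unit_rms_noise(n=12000, seed=8)
        a = mix_at_snr(speech, masker, 5.0, seed=42)
        b = mix_at_snr(speech, masker, 5.0, seed=42)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert a.n_samples == speech.n_samples

    def test_errors(self):
        speech = unit_rms_noise(seed=9)
        with pytest.raises(ValueError, match="zero RMS"):
            mix_at_snr(Waveform(np.zeros(100), RATE), unit_rms_noise(100), 0.0)
        with pytest.raises(ValueError, match="zero RMS"):
            mix_at_snr(unit_rms_noise(100), Waveform(np.zeros(100), RATE), 0.0)
        with pytest.raises(ValueError, match="rate mismatch"):
            mix_at_snr(speech, Waveform(speech.samples, 2 * RATE), 0.0)
        with pytest.raises(ValueError, match="at least as long"):
            mix_at_snr(speech, unit_rms_noise(100), 0.0)


class TestNormalizeMixture:
    def test_mixture_rms_scales_to_target(self):
        mix = Waveform(0.2 * unit_rms_noise(seed=1).samples, RATE)
        out = normalize_mixture(mix, MixtureSpec(0.0, "mixture_rms", 0.1))
        np.testing.assert_allclose(out.samples, 0.5 * mix.samples, rtol=1e-12)
        assert abs(out.rms() - 0.1) < 1e-9

    def test_speech_rms_is_identity(self):
        mix = unit_rms_noise(seed=2)
        out = normalize_mixture(mix, MixtureSpec(0.0, "speech_rms", 0.1))
        np.testing.assert_array_equal(out.samples, mix.samples)

    def test_clear_speech_fixed_point(self):
        clear = unit_rms_noise(seed=3)
        out = normalize_mixture(
            clear, MixtureSpec(0.0, "mixture_rms", clear.rms())
        )
        np.testing.assert_allclose(out.samples, clear.samples, rtol=1e-12)

    def test_commutes_with_global_scaling(self):
        speech, masker = unit_rms_noise(seed=4), unit_rms_noise(seed=5)
        spec = MixtureSpec(6.0, "mixture_rms", 0.05)
        mix = mix_at_snr(speech, masker, 6.0)
        scaled_mix = mix_at_snr(
            Waveform(3.0 * speech.samples, RATE),
            Waveform(3.0 * masker.samples, RATE),
            6.0,
        )
        a = normalize_mixture(mix, spec)
        b = normalize_mixture(scaled_mix, spec)
        np.testing.assert_allclose(a.samples, b.samples, rtol=1e-9)

    def test_zero_rms_error(self):
        with pytest.raises(ValueError, match="zero-RMS"):
            normalize_mixture(
                Waveform(np.zeros(10), RATE), MixtureSpec(0.0, "mixture_rms", 0.1)
            )

    def test_unknown_normalization_rejected(self):
        with pytest.raises(ValueError, match="unknown normalization"):
            MixtureSpec(0.0, "peak", 0.1)


class TestSpectrallyMatchedNoise:
    def test_magnitude_spectrum_matches(self, noise_wave):
        out = spectrally_matched_noise(noise_wave, seed=0)
        assert out.n_samples == noise_wave.n_samples and out.rate == noise_wave.rate
        m_in = np.abs(np.fft.rfft(noise_wave.samples))
        m_out = np.abs(np.fft.rfft(out.samples))
        nz = m_in > 1e-12 * m_in.max()
        assert np.max(np.abs(m_out[nz] - m_in[nz]) / m_in[nz]) < 1e-6

    def test_pure_sine_stays_single_bin(self):
        n = 4096
        k = 37
        sine = Waveform(np.sin(2 * np.pi * k * np.arange(n) / n), RATE)
        out = spectrally_matched_noise(sine, seed=1)
        spec = np.abs(np.fft.rfft(out.samples))
        assert np.argmax(spec) == k
        others = np.delete(spec, k)
        assert others.max() < 1e-6 * spec[k]

    def test_seeded_determinism(self, noise_wave):
        a = spectrally_matched_noise(noise_wave, seed=7)
        b = spectrally_matched_noise(noise_wave, seed=7)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_spectrum_invariant_under_reapplication(self, noise_wave):
        once = spectrally_matched_noise(noise_wave, seed=2)
        twice = spectrally_matched_noise(once, seed=3)
        m1 = np.abs(np.fft.rfft(once.samples))
        m2 = np.abs(np.fft.rfft(twice.samples))
        np.testing.assert_allclose(m2, m1, rtol=1e-6, atol=1e-9 * m1.max())


class TestSynthNoise:
    @pytest.mark.parametrize(
        "kind,lo,hi", [("white", -0.1, 0.1), ("pink", -1.15, -0.85)]
    )
    def test_psd_slope(self, kind, lo, hi):
        wave = synth_noise(kind, 2**17, RATE, seed=0)
        f, p = signal.welch(wave.samples, fs=RATE, nperseg=4096)
        sel = (f > 10) & (f < RATE / 4)
        slope = np.polyfit(np.log10(f[sel]), np.log10(p[sel]), 1)[0]
        assert lo <= slope <= hi

    def test_zero_mean_unit_rms_and_determinism(self):
        a = synth_noise("pink", 4096, RATE, seed=3)
        b = synth_noise("pink", 4096, RATE, seed=3)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert abs(a.samples.mean()) < 1e-12
        assert abs(a.rms() - 1.0) < 1e-12

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="unknown noise kind"):
            synth_noise("brown", 100, RATE, seed=0)


class TestMakeBabble:
    def test_coherent_sum_of_copies(self):
        stream = unit_rms_noise(seed=1)
        out = make_babble([stream.copy() for _ in range(12)], seed=0)
        # coherent sum of identical streams is proportional to the stream
        np.testing.assert_allclose(
            out.samples, stream.samples / stream.rms(), rtol=1e-9
        )

    def test_independent_streams_rms_sqrt12(self):
        streams = [unit_rms_noise(n=30000, seed=s) for s in range(12)]
        raw_sum = np.sum([s.samples for s in streams], axis=0)
        pre_norm_rms = np.sqrt(np.mean(raw_sum**2))
        assert abs(pre_norm_rms - np.sqrt(12)) / np.sqrt(12) < 0.05
        out = make_babble(streams, seed=0)
        np.testing.assert_allclose(out.samples, raw_sum / pre_norm_rms, rtol=1e-9)
        assert abs(out.rms() - 1.0) < 1e-12

    def test_too_few_streams(self):
        with pytest.raises(ValueError, match="at least 12"):
            make_babble([unit_rms_noise(seed=s) for s in range(11)])


class TestConditionGrid:
    def test_experiment_grid_endpoints(self):
        grid = ConditionGrid.from_range(30.0, 1.6, 21)
        assert grid.n_levels == 21
        assert abs(grid.snr_levels_db.min() - (-2.0)) < 1e-9
        assert abs(grid.snr_levels_db.max() - 30.0) < 1e-9
        steps = np.diff(grid.snr_levels_db)
        np.testing.assert_allclose(steps, -1.6, rtol=1e-12)

    def test_levels_must_decrease(self):
        with pytest.raises(ValueError, match="strictly decreasing"):
            ConditionGrid(np.array([0.0, 5.0, 10.0]))
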