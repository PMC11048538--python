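"""Filtering, STFT, cropping, resizing and image assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegaug.preprocess import (STFTParams, band_crop, bandpass, normalize_image,
                               notch, preprocess_dataset, preprocess_trial,
                               resize_map, row_band_map, stack_and_normalize,
                               stft_magnitude)
from eegaug.synth import SynthConfig, EEGTrial, generate_trial


def _tone(freq, fs=250.0, T=1000):
    x = np.sin(2 * np.pi * freq * np.arange(T) / fs)
    return EEGTrial(samples=np.tile(x, (3, 1)), label="left", sample_rate=fs,
                    trial_id=f"tone{freq}")


def _rms(x):
    return np.sqrt(np.mean(x**2))


class TestFilters:
    def test_bandpass_stopband_and_passband(self):
        out50 = bandpass(_tone(50.0), 0.5, 40.0)
        assert _rms(out50.samples) < 0.05 * _rms(_tone(50.0).samples)
        out10 = bandpass(_tone(10.0), 0.5, 40.0)
        assert _rms(out10.samples) == pytest.approx(_rms(_tone(10.0).samples),
                                                    rel=0.05)

    def test_bandpass_zero_and_errors(self):
        zero = EEGTrial(samples=np.zeros((3, 1000)), label="left",
                        sample_rate=250.0, trial_id="z")
        np.testing.assert_allclose(bandpass(zero, 0.5, 40).samples, 0.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(_tone(10), 0.5, 130.0)

    def test_notch_attenuates_mains_only(self):
        out50 = notch(_tone(50.0))
        assert _rms(out50.samples) < 0.10 * _rms(_tone(50.0).samples)
        out10 = notch(_tone(10.0))
        assert abs(_rms(out10.samples) - _rms(_tone(10.0).samples)) \
            <= 0.05 * _rms(_tone(10.0).samples)
        zero = EEGTrial(samples=np.zeros((3, 500)), label="left",
                        sample_rate=250.0, trial_id="z")
        np.testing.assert_allclose(notch(zero).samples, 0.0)


class TestSTFT:
    def test_frame_count_and_peak_bin(self):
        p = STFTParams(log_power=False)
        spec = stft_magnitude(_tone(10.0).samples[0], 250.0, p)
        assert spec.shape == (257, 28)  # floor((1000-128)/32)+1 frames
        assert np.unravel_index(spec.argmax(), spec.shape)[0] == 20  # 10*512/250

    def test_first_frame_matches_direct_dft(self):
        """One tapered frame put through numpy's rfft directly."""
        p = STFTParams(log_power=False)
        x = np.sin(2 * np.pi * 10.0 * np.arange(1000) / 250.0)
        spec = stft_magnitude(x, 250.0, p)
        from scipy.signal import get_window
        frame = x[:128] * get_window("hann", 128, fftbins=True)
        np.testing.assert_allclose(spec[:, 0], np.abs(np.fft.rfft(frame, n=512)),
                                   atol=1e-12)

    def test_zero_signal_and_short_signal(self):
        p = STFTParams(log_power=False)
        np.testing.assert_array_equal(stft_magnitude(np.zeros(500), 250.0, p), 0.0)
        with pytest.raises(ValueError, match="128"):
            stft_magnitude(np.zeros(100), 250.0, p)

    def test_band_crop_bin_enumeration(self):
        spec = np.arange(257)[:, None] * np.ones((1, 5))
        out = band_crop(spec, 250.0, 512, (0.5, 40.0))
        assert out.shape[0] == 80
        assert out[0, 0] == 2 and out[-1, 0] == 81  # rows 2..81 retained
        full = band_crop(spec, 250.0, 512, (0.0, 125.0))
        assert full.shape[0] == 257
        with pytest.raises(ValueError):
            band_crop(spec, 250.0, 512, (200.0, 220.0))


class TestResizeAndStack:
    def test_resize_shapes_and_identities(self):
        src = np.random.default_rng(0).random((80, 28))
        assert resize_map(src, (11, 33)).shape == (11, 33)
        np.testing.assert_allclose(resize_map(np.full((5, 7), 3.3), (11, 33)), 3.3)
        np.testing.assert_allclose(resize_map(src, (80, 28)), src, atol=1e-12)
        with pytest.raises(ValueError, match="degenerate"):
            resize_map(src, (0, 33))

    def test_stack_order_and_normalization(self):
        p = STFTParams()
        ones = np.ones((11, 33))
        zeros = np.zeros((11, 33))
        img = stack_and_normalize(ones, zeros, zeros, p)
        assert img.pixels.shape == (32, 32)
        # C3 occupies the top third: top rows strictly brighter than bottom
        assert img.pixels[:9].mean() > img.pixels[-9:].mean()
        assert img.pixels[:9].min() > img.pixels[-9:].max() - 1e-9
        const = stack_and_normalize(ones, ones, ones, p)
        np.testing.assert_allclose(const.pixels, 0.5)
        with pytest.raises(ValueError, match="Cz"):
            stack_and_normalize(ones, np.ones((12, 33)), ones, p)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_normalization_idempotent(self, seed):
        img = np.random.default_rng(seed).random((32, 32))
        once = normalize_image(img)
        twice = normalize_image(once)
        assert np.max(np.abs(once - twice)) <= 1e-12


class TestPipeline:
    def test_single_trial_shape_and_range(self, synth_cfg):
        t = generate_trial("right", synth_cfg, np.random.default_rng(0))
        img = preprocess_trial(t)
        assert img.pixels.shape == (32, 32)
        assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0
        assert img.label == "right" and img.kind == "real"

    def test_dataset_preserves_counts_and_order(self, small_trials, small_images):
        assert len(small_images) == len(small_trials)
        assert small_images.class_counts() == small_trials.class_counts()
        assert [im.source_id for im in small_images] == \
            [t.trial_id for t in small_trials]

    def test_short_trial_raises_with_trial_id(self):
        t = EEGTrial(samples=np.zeros((3, 100)), label="left", sample_rate=250.0,
                     trial_id="short-one")
        with pytest.raises(ValueError, match="short-one"):
            preprocess_trial(t)

    def test_energy_localizes_in_mu_rows(self):
        """A mu-only rhythm lights up the mu rows of each channel block."""
        cfg = SynthConfig(beta_amp=0.0, noise_amp=0.05)
        t = generate_trial("left", cfg, np.random.default_rng(2))
        img = preprocess_trial(t)
        rbm = row_band_map()
        for ch, block in (("C3", slice(0, 11)), ("Cz", slice(11, 21)),
                          ("C4", slice(21, 32))):
            mu_rows = rbm[ch]["mu"]
            other = [r for r in range(block.start, block.stop)
                     if r not in mu_rows]
            assert img.pixels[mu_rows].mean() > img.pixels[other].mean()


def test_row_band_map_covers_all_channels():
    rbm = row_band_map()
    for ch in ("C3", "Cz", "C4"):
        assert rbm[ch]["mu"] and rbm[ch]["beta"]
        assert not set(rbm[ch]["mu"]) & set(rbm[ch]["beta"])
    all_rows = [r for ch in rbm for b in rbm[ch] for r in rbm[ch][b]]
    assert min(all_rows) >= 0 and max(all_rows) <= 31
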