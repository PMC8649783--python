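"""Spectrogram, normalization, fusion-layout and signal-image contracts."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.signal import windows as sw

import biofusion as bf
from biofusion.imaging import LAYOUTS, modality_of
from biofusion.session import CHANNEL_NAMES


def _tone(freq, n=1000, fs=4000.0):
    return np.sin(2 * np.pi * freq * np.arange(n) / fs)


class TestSpectrogram:
    @pytest.mark.parametrize("modality", ["EEG", "EMG"])
    def test_dimensions(self, modality):
        img = bf.spectrogram(np.random.default_rng(0).random(1000), modality)
        assert img.shape == (32, 68)  # 32 frequency bins x 68 time frames

    def test_matches_bruteforce_fft(self):
        """Cropped bins equal a zero-padded Hann-tapered FFT, frame by frame."""
        x = np.random.default_rng(1).standard_normal(1000)
        taper = sw.hann(56, sym=False)
        for modality, fft_len in (("EEG", 3200), ("EMG", 256)):
            img = bf.spectrogram(x, modality)
            for frame in (0, 33, 67):
                seg = x[frame * 14: frame * 14 + 56] * taper
                ref = np.abs(np.fft.rfft(seg, n=fft_len))[1:33]
                np.testing.assert_allclose(img[:, frame], ref,
                                           rtol=1e-4, atol=1e-5)

    @pytest.mark.parametrize("freq,row", [
        (250.0, 15),   # 250 / 15.625 = bin 16 -> row 15
        (312.5, 19),   # bin 20
    ])
    def test_emg_tone_localization(self, freq, row):
        """Tones above the 56-sample window bandwidth land in their bin."""
        img = bf.spectrogram(_tone(freq), "EMG")
        assert np.all(img.argmax(axis=0) == row)

    def test_zero_input_zero_image(self):
        assert not bf.spectrogram(np.zeros(1000), "EEG").any()

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            bf.spectrogram(np.zeros(40), "EEG")

    def test_crop_bin_counts(self):
        crop = bf.CropSpec()
        assert crop.bin_slice("EEG", 3200, 4000.0) == slice(1, 33)
        assert crop.bin_slice("EMG", 256, 4000.0) == slice(1, 33)


class TestNormalization:
    def test_affine_map(self):
        stats = bf.NormalizationStats("S", "EEG", 2.0, 10.0)
        out = bf.apply_normalization(np.array([2.0, 4.0, 10.0]), stats)
        np.testing.assert_allclose(out, [0.0, 0.25, 1.0])

    def test_constant_collection_maps_to_zero(self):
        stats = bf.fit_normalization(np.full(10, 3.3), "S", "EMG")
        assert not bf.apply_normalization(np.full(10, 3.3), stats).any()

    def test_subject_extrema_hit_unit_interval(self, small_windows):
        ds = bf.build_image_dataset(small_windows, "grouped")
        eeg_part = ds.images[:, :96, :]   # top three 32-row blocks are EEG
        emg_part = ds.images[:, 96:, :]
        for block in (eeg_part, emg_part):
            assert block.min() == 0.0
            assert block.max() == 1.0

    def test_order_independence(self, small_windows):
        a = bf.build_image_dataset(small_windows, "grouped")
        rev = small_windows.samples[::-1].copy()
        ws2 = bf.WindowSet(
            subject_id=small_windows.subject_id,
            sampling_rate=small_windows.sampling_rate,
            samples=rev,
            weight_class=small_windows.weight_class[::-1].copy(),
            weight_label=small_windows.weight_label[::-1].copy(),
            speed_label=small_windows.speed_label[::-1].copy(),
            trial_index=small_windows.trial_index[::-1].copy(),
            rep_index=small_windows.rep_index[::-1].copy(),
            window_index=small_windows.window_index[::-1].copy(),
            class_weights=small_windows.class_weights,
        )
        b = bf.build_image_dataset(ws2, "grouped")
        np.testing.assert_allclose(a.images, b.images[::-1], atol=1e-6)


class TestLayouts:
    @pytest.mark.parametrize("layout,shape", [
        ("grouped", (160, 68)),
        ("mixed", (160, 68)),
        ("eeg_stack", (96, 68)),
        ("emg_stack", (64, 68)),
        ("stacked", (32, 68, 5)),
        ("eeg_multi", (32, 68, 3)),
        ("emg_multi", (32, 68, 2)),
        ("signal_full", (5, 1000)),
        ("signal_eeg", (3, 1000)),
        ("signal_emg", (2, 1000)),
    ])
    def test_dataset_shapes_and_range(self, small_windows, layout, shape):
        ds = bf.build_image_dataset(small_windows, layout)
        assert ds.input_shape == shape
        assert 0.0 <= ds.images.min() and ds.images.max() <= 1.0

    def test_mixed_is_grouped_row_permutation(self, small_windows):
        g = bf.build_image_dataset(small_windows, "grouped")
        m = bf.build_image_dataset(small_windows, "mixed")
        blocks = {c: g.images[:, 32 * i:32 * (i + 1), :]
                  for i, c in enumerate(g.row_order)}
        rebuilt = np.concatenate([blocks[c] for c in m.row_order], axis=1)
        np.testing.assert_array_equal(rebuilt, m.images)

    def test_stacked_depth_identity(self, small_windows):
        g = bf.build_image_dataset(small_windows, "grouped")
        s = bf.build_image_dataset(small_windows, "stacked")
        for i, c in enumerate(s.row_order):
            block = g.images[:, 32 * g.row_order.index(c):
                             32 * (g.row_order.index(c) + 1), :]
            np.testing.assert_array_equal(s.images[..., i], block)

    def test_pixel_multisets_agree_across_fusions(self, small_windows):
        imgs = {layout: bf.build_image_dataset(small_windows, layout).images
                for layout in ("grouped", "mixed", "stacked")}
        for w in range(len(small_windows)):
            ref = np.sort(imgs["grouped"][w].ravel())
            for other in ("mixed", "stacked"):
                np.testing.assert_array_equal(
                    np.sort(imgs[other][w].ravel()), ref)

    def test_assemble_layout_requires_all_channels(self):
        imgs = {c: np.zeros((32, 68)) for c in CHANNEL_NAMES[:4]}
        with pytest.raises(ValueError, match="triceps"):
            bf.assemble_layout(imgs, "grouped")

    def test_assemble_vertical_and_depth(self):
        rng = np.random.default_rng(2)
        imgs = {c: rng.random((32, 68)) for c in CHANNEL_NAMES}
        v = bf.assemble_layout(imgs, "grouped")
        d = bf.assemble_layout(imgs, "stacked")
        assert v.shape == (160, 68) and d.shape == (32, 68, 5)
        np.testing.assert_array_equal(v[:32], imgs["C3"])
        np.testing.assert_array_equal(d[..., 3], imgs["biceps"])


class TestSignalImages:
    def _stats(self):
        return (bf.NormalizationStats("S", "EEG", -0.01, 0.01),
                bf.NormalizationStats("S", "EMG", -1.0, 1.0))

    def test_shape_and_row_order(self):
        w = np.random.default_rng(0).uniform(-0.01, 0.01, (5, 1000))
        img = bf.signal_image(w, *self._stats())
        assert img.shape == (5, 1000)

    @pytest.mark.parametrize("layout,height", [
        ("signal_eeg", 3), ("signal_emg", 2)])
    def test_modality_subsets(self, layout, height):
        w = np.zeros((5, 1000))
        img = bf.signal_image(w, *self._stats(), layout=layout)
        assert img.shape == (height, 1000)

    def test_per_modality_scaling_balances_amplitudes(self):
        # EMG rows 100x larger than EEG rows before normalization
        rng = np.random.default_rng(3)
        w = np.empty((5, 1000))
        w[:3] = 0.01 * rng.uniform(-1, 1, (3, 1000))
        w[3:] = 1.0 * rng.uniform(-1, 1, (2, 1000))
        se = bf.fit_normalization(w[:3], "S", "EEG")
        sm = bf.fit_normalization(w[3:], "S", "EMG")
        img = bf.signal_image(w, se, sm)
        ranges = img.max(axis=1) - img.min(axis=1)
        assert ranges.min() > 0.5  # all rows span a comparable [0,1] range

    def test_missing_stats_rejected(self):
        with pytest.raises(ValueError, match="stats"):
            bf.signal_image(np.zeros((5, 1000)), None,
                            bf.NormalizationStats("S", "EMG", 0, 1))


def test_layout_registry_modalities():
    for name, (kind, order) in LAYOUTS.items():
        assert all(modality_of(c) in ("EEG", "EMG") for c in order)
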