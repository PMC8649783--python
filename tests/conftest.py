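"""Shared fixtures: small synthetic sessions reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import biofusion as bf


@pytest.fixture(scope="session")
def short_spec() -> bf.SessionSpec:
    """A trimmed session (short reps) that keeps the factorial structure."""
    return bf.SessionSpec(subject_id="T01", slow_duration=4.0,
                          fast_duration=2.0, rng_seed=7)


@pytest.fixture(scope="session")
def recording(short_spec) -> bf.Recording:
    return bf.generate_recording(short_spec, bf.EffectModel())


@pytest.fixture(scope="session")
def windows(recording) -> bf.WindowSet:
    rec = bf.segment_movement(bf.filter_recording(recording))
    return bf.make_windows(rec)


@pytest.fixture(scope="session")
def small_windows(windows) -> bf.WindowSet:
    """First 12 windows only, for layout/identity tests."""
    idx = np.arange(12)
    return bf.WindowSet(
        subject_id=windows.subject_id,
        sampling_rate=windows.sampling_rate,
        samples=windows.samples[idx],
        weight_class=windows.weight_class[idx],
        weight_label=windows.weight_label[idx],
        speed_label=windows.speed_label[idx],
        trial_index=windows.trial_index[idx],
        rep_index=windows.rep_index[idx],
        window_index=windows.window_index[idx],
        class_weights=windows.class_weights,
    )


@pytest.fixture
def tiny_hp() -> dict:
    """A small, always-feasible hyperparameter assignment."""
    return {
        "kernels": [3, 3, 3],
        "filters": [8, 8, 8],
        "dropout_conv": [0.0, 0.0, 0.0],
        "units": [20, 20],
        "dropout_fc": [0.0, 0.0],
        "adam_lr": 1e-3,
    }


def make_blob_dataset(n_per_class: int = 60, size: int = 12, seed: int = 0):
    """Linearly separable toy images: bright top, bright bottom, blank.

    Returns (images, labels) with images (N, size, size) in [0, 1].
    """
    rng = np.random.default_rng(seed)
    images, labels = [], []
    half = size // 2
    for c in range(3):
        for _ in range(n_per_class):
            img = 0.05 * rng.random((size, size))
            if c == 0:
                img[:half] += 0.8
            elif c == 1:
                img[half:] += 0.8
            images.append(np.clip(img, 0, 1))
            labels.append(c)
    order = rng.permutation(len(images))
    return (np.array(images, np.float32)[order],
            np.array(labels, np.int64)[order])
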