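"""Seeded synthetic EEG/EMG session generator.

The generator emulates the structure of an elbow flexion-extension session
so the full pipeline can be exercised end to end: per repetition, the two
EMG channels are band-limited (20-500 Hz) stochastic carriers shaped by a
phase-locked envelope -- biceps active during the flexion half of the
repetition, triceps during the extension half -- with amplitude growing
multiplicatively with task weight and with movement speed.  The three EEG
channels are a 1/f background plus mu (8-12 Hz) and beta (13-30 Hz)
oscillations whose power drops during movement in proportion to weight
(event-related desynchronization).  Occasional low-frequency high-amplitude
transients on all channels emulate motion artifacts.

Everything is driven by one RNG stream per recording, derived from
``(rng_seed, subject_id)``, so subjects are independent but reproducible.
"""

from __future__ import annotations

import zlib

import numpy as np
from scipy import signal

from .session import (
    EEG_ROWS,
    EMG_ROWS,
    EffectModel,
    Recording,
    Repetition,
    SessionSpec,
    Trial,
)

# Amplitude scales, mV.  EMG is ~100x EEG so the per-modality
# normalization downstream has real work to do.
_EMG_BASE_MV = 1.0
_EEG_BASE_MV = 0.01
# Rest margin recorded on either side of the movement, seconds.
_REST_MARGIN_S = 0.5


def _rng_for(spec: SessionSpec) -> np.random.Generator:
    sid = zlib.crc32(spec.subject_id.encode())
    return np.random.default_rng(np.random.SeedSequence([spec.rng_seed, sid]))


def _bandpassed_noise(rng: np.random.Generator, n: int, fs: float,
                      lo: float, hi: float, order: int = 4) -> np.ndarray:
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    # unit RMS so envelopes control amplitude directly
    rms = np.sqrt(np.mean(x**2))
    return x / max(rms, 1e-12)


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """1/f-spectrum noise via FFT amplitude shaping, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / np.sqrt(np.mean(x**2))


def _movement_envelopes(n_move: int) -> tuple[np.ndarray, np.ndarray]:
    """Raised-cosine activation for the flexion and extension half-cycles."""
    t = np.linspace(0.0, 1.0, n_move, endpoint=False)
    flex = np.where(t < 0.5, 0.5 * (1 - np.cos(2 * np.pi * t / 0.5)), 0.0)
    ext = np.where(t >= 0.5, 0.5 * (1 - np.cos(2 * np.pi * (t - 0.5) / 0.5)), 0.0)
    return flex, ext


def _add_artifacts(rng: np.random.Generator, samples: np.ndarray,
                   fs: float, rate: float, scale: np.ndarray) -> None:
    """Superimpose low-frequency (<5 Hz) transients on all channels."""
    duration = samples.shape[1] / fs
    n_events = rng.poisson(rate * duration)
    width = int(0.4 * fs)  # 0.4 s transient -> ~2.5 Hz dominant frequency
    bump = 0.5 * (1 - np.cos(2 * np.pi * np.arange(width) / width))
    for _ in range(n_events):
        start = rng.integers(0, max(samples.shape[1] - width, 1))
        amp = rng.uniform(5.0, 10.0)
        sign = rng.choice((-1.0, 1.0))
        samples[:, start:start + width] += (
            sign * amp * scale[:, None] * bump[None, : samples.shape[1] - start]
        )


def _generate_repetition(rng: np.random.Generator, spec: SessionSpec,
                         effects: EffectModel, speed_label: str,
                         duration: float, weight: float,
                         rep_index: int) -> Repetition:
    fs = spec.sampling_rate
    n_margin = int(round(_REST_MARGIN_S * fs))
    n_move = int(round(duration * fs))
    n_total = n_move + 2 * n_margin
    start, end = n_margin, n_margin + n_move

    samples = np.zeros((5, n_total))
    flex, ext = _movement_envelopes(n_move)

    # EMG: shaped carrier inside the movement window, faint tone at rest.
    weight_gain = 1.0 + effects.emg_gain_per_lb * weight
    speed_gain = effects.speed_gain if speed_label == "fast" else 1.0
    emg_hi = 500.0 - effects.emg_fatigue_spectral_shift * rep_index
    for row, env in zip(EMG_ROWS, (flex, ext)):
        carrier = _bandpassed_noise(rng, n_total, fs, 20.0, min(emg_hi, fs / 2 - 1))
        shape = np.full(n_total, 0.05)
        shape[start:end] += env
        samples[row] = _EMG_BASE_MV * weight_gain * speed_gain * carrier * shape

    # EEG: 1/f background + mu/beta rhythms with weight-dependent ERD.
    erd = effects.eeg_erd_depth_per_lb * weight
    amp_factor = np.sqrt(1.0 - erd)  # power reduction -> amplitude factor
    for row in EEG_ROWS:
        background = 0.6 * _pink_noise(rng, n_total)
        mu = 0.3 * _bandpassed_noise(rng, n_total, fs, 8.0, 12.0)
        beta = 0.2 * _bandpassed_noise(rng, n_total, fs, 13.0, 30.0)
        rhythm_gain = np.ones(n_total)
        rhythm_gain[start:end] = amp_factor
        eeg = background + rhythm_gain * (mu + beta)
        eeg += effects.noise_sd * rng.standard_normal(n_total)
        samples[row] = _EEG_BASE_MV * eeg

    if effects.artifact_rate > 0:
        scale = np.array([_EEG_BASE_MV] * 3 + [_EMG_BASE_MV] * 2)
        _add_artifacts(rng, samples, fs, effects.artifact_rate, scale)

    return Repetition(samples.astype(np.float32), start, end)


def generate_recording(spec: SessionSpec,
                       effects: EffectModel | None = None) -> Recording:
    """Generate one subject's session.

    Returns a :class:`Recording` with |speeds| x |weights| trials of
    ``spec.reps_per_trial`` repetitions each; identical ``(spec, effects)``
    yield bit-identical sample arrays.
    """
    effects = effects or EffectModel()
    effects.validate_for(spec)
    rng = _rng_for(spec)
    trials = []
    for speed_label, duration in spec.speeds:
        for weight in spec.weights:
            reps = [
                _generate_repetition(rng, spec, effects, speed_label,
                                     duration, weight, r)
                for r in range(spec.reps_per_trial)
            ]
            trials.append(Trial(speed_label, float(weight), reps))
    return Recording(spec.subject_id, spec.sampling_rate, trials)
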