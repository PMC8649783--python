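"""Software filtering, movement segmentation, and sliding-window cutting.

EEG channels are band-passed 0.5-40 Hz (3rd-order Butterworth) and EMG
channels are DC-corrected then band-passed 20-500 Hz (4th order), both
applied forward-backward (zero phase) as is standard for offline pipelines.
Movement is isolated with the per-repetition start/end markers, and the
movement portion is cut into 250 ms windows with 50% overlap (1000 samples
and a 500-sample step at 4000 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .session import EEG_ROWS, EMG_ROWS, Recording, Repetition, Trial


@dataclass(frozen=True)
class FilterSpec:
    eeg_band: tuple[float, float] = (0.5, 40.0)
    eeg_order: int = 3
    emg_band: tuple[float, float] = (20.0, 500.0)
    emg_order: int = 4
    emg_dc_removal: bool = True

    def validate(self, fs: float) -> None:
        for lo, hi in (self.eeg_band, self.emg_band):
            if not (0 < lo < hi):
                raise ValueError(f"invalid band ({lo}, {hi})")
            if hi >= fs / 2:
                raise ValueError(
                    f"band edge {hi} Hz at or above Nyquist ({fs / 2} Hz)"
                )


@dataclass(frozen=True)
class WindowSpec:
    """250 ms windows with 50% overlap."""

    length_s: float = 0.25
    overlap: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.overlap < 1):
            raise ValueError("overlap must be in [0, 1)")

    def length_samples(self, fs: float) -> int:
        return int(round(self.length_s * fs))

    def step_samples(self, fs: float) -> int:
        return int(round(self.length_s * fs * (1 - self.overlap)))


@dataclass
class WindowSet:
    """Labeled fixed-length windows cut from a recording.

    ``samples`` is (W, 5, L); per-window metadata arrays are parallel.
    ``weight_class`` encodes weights in increasing order (0 lbs -> 0,
    3 lbs -> 1, 5 lbs -> 2 under the default levels).
    """

    subject_id: str
    sampling_rate: float
    samples: np.ndarray                      # (W, 5, L) float32
    weight_class: np.ndarray                 # (W,) int
    weight_label: np.ndarray                 # (W,) float, lbs
    speed_label: np.ndarray                  # (W,) str
    trial_index: np.ndarray                  # (W,) int
    rep_index: np.ndarray                    # (W,) int
    window_index: np.ndarray                 # (W,) int, within repetition
    class_weights: tuple[float, ...] = field(default=(0.0, 3.0, 5.0))

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def n_classes(self) -> int:
        return len(self.class_weights)


def _design(spec: FilterSpec, fs: float):
    eeg_sos = signal.butter(spec.eeg_order, spec.eeg_band, btype="bandpass",
                            fs=fs, output="sos")
    emg_sos = signal.butter(spec.emg_order, spec.emg_band, btype="bandpass",
                            fs=fs, output="sos")
    return eeg_sos, emg_sos


def filter_recording(rec: Recording, fspec: FilterSpec | None = None) -> Recording:
    """Zero-phase band-pass filtering per modality; markers unchanged."""
    fspec = fspec or FilterSpec()
    fspec.validate(rec.sampling_rate)
    eeg_sos, emg_sos = _design(fspec, rec.sampling_rate)

    def apply(samples: np.ndarray) -> np.ndarray:
        out = np.empty_like(samples, dtype=np.float64)
        eeg = samples[list(EEG_ROWS)].astype(np.float64)
        emg = samples[list(EMG_ROWS)].astype(np.float64)
        if fspec.emg_dc_removal:
            emg = emg - emg.mean(axis=1, keepdims=True)
        out[list(EEG_ROWS)] = signal.sosfiltfilt(eeg_sos, eeg, axis=1)
        out[list(EMG_ROWS)] = signal.sosfiltfilt(emg_sos, emg, axis=1)
        return out.astype(samples.dtype)

    return rec.map_samples(apply)


def segment_movement(rec: Recording) -> Recording:
    """Truncate every repetition to its [start_marker, end_marker) span."""
    trials = []
    for ti, t in enumerate(rec.trials):
        reps = []
        for ri, r in enumerate(t.reps):
            if r.start_marker >= r.end_marker:
                raise ValueError(
                    f"trial {ti} rep {ri}: inverted markers "
                    f"({r.start_marker}, {r.end_marker})"
                )
            cut = r.samples[:, r.start_marker:r.end_marker]
            reps.append(Repetition(cut, 0, cut.shape[1]))
        trials.append(Trial(t.speed_label, t.weight_label, reps))
    return Recording(rec.subject_id, rec.sampling_rate, trials)


def window_count(n: int, length: int, step: int) -> int:
    """Number of full windows in n samples (no padding)."""
    return (n - length) // step + 1 if n >= length else 0


def make_windows(rec: Recording, wspec: WindowSpec | None = None) -> WindowSet:
    """Cut every repetition into fixed-length overlapping windows.

    Windows start at 0, step, 2*step, ... while they fit entirely inside
    the repetition; trailing partial windows are discarded.  Labels are
    copied from the trial metadata.
    """
    wspec = wspec or WindowSpec()
    fs = rec.sampling_rate
    length = wspec.length_samples(fs)
    step = wspec.step_samples(fs)

    class_weights = tuple(sorted({float(t.weight_label) for t in rec.trials}))
    cls_of = {w: i for i, w in enumerate(class_weights)}

    chunks, meta = [], {k: [] for k in
                        ("wc", "wl", "sp", "ti", "ri", "wi")}
    for ti, t in enumerate(rec.trials):
        for ri, r in enumerate(t.reps):
            n = r.n_samples
            for wi in range(window_count(n, length, step)):
                s = wi * step
                chunks.append(r.samples[:, s:s + length])
                meta["wc"].append(cls_of[float(t.weight_label)])
                meta["wl"].append(float(t.weight_label))
                meta["sp"].append(t.speed_label)
                meta["ti"].append(ti)
                meta["ri"].append(ri)
                meta["wi"].append(wi)

    samples = (np.stack(chunks).astype(np.float32) if chunks
               else np.empty((0, 5, length), np.float32))
    return WindowSet(
        subject_id=rec.subject_id,
        sampling_rate=fs,
        samples=samples,
        weight_class=np.array(meta["wc"], dtype=np.int64),
        weight_label=np.array(meta["wl"], dtype=np.float64),
        speed_label=np.array(meta["sp"], dtype=object),
        trial_index=np.array(meta["ti"], dtype=np.int64),
        rep_index=np.array(meta["ri"], dtype=np.int64),
        window_index=np.array(meta["wi"], dtype=np.int64),
        class_weights=class_weights,
    )
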