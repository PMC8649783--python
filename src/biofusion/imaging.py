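"""CNN input images: STFT spectrograms, fusion layouts, signal images.

Each 250 ms window becomes either a time-frequency image or a time-domain
image.  Spectrograms use a 56-sample Hann window with 75% overlap (hop 14),
giving 68 time frames per 1000-sample window, and modality-specific FFT
lengths (3200 for EEG, 256 for EMG) chosen so that cropping each modality
to its bandwidth of interest (0.5-40 Hz EEG, 20-500 Hz EMG) keeps exactly
32 frequency bins.  Pixel values are linear STFT magnitudes, min-max
normalized per subject and per modality so EEG and EMG occupy comparable
[0, 1] ranges despite their ~100x amplitude difference.

Arrays are stored height x width: a single-channel spectrogram is (32, 68)
(frequency low->high along rows, time along columns), a vertically fused
image is (160, 68), a depth-stacked image (32, 68, 5), and a signal image
(5, 1000).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import windows as _windows

from .preprocess import WindowSet
from .session import CHANNEL_NAMES, EEG_ROWS, EMG_ROWS

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StftSpec:
    win_len: int = 56
    overlap: float = 0.75
    fft_len_eeg: int = 3200
    fft_len_emg: int = 256
    window_fn: str = "hann"
    log_magnitude: bool = False  # default: plain linear |STFT|

    def __post_init__(self) -> None:
        hop = self.win_len * (1 - self.overlap)
        if abs(hop - round(hop)) > 1e-9 or hop <= 0:
            raise ValueError("win_len * (1 - overlap) must be a positive integer")
        if min(self.fft_len_eeg, self.fft_len_emg) < self.win_len:
            raise ValueError("fft length must be >= win_len")

    @property
    def hop(self) -> int:
        return int(round(self.win_len * (1 - self.overlap)))

    def fft_len(self, modality: str) -> int:
        return self.fft_len_eeg if modality == "EEG" else self.fft_len_emg

    def taper(self) -> np.ndarray:
        return _windows.get_window(self.window_fn, self.win_len, fftbins=True)


@dataclass(frozen=True)
class CropSpec:
    """Keep FFT bins 1 .. floor(f_high / df); the DC bin is dropped.

    With the default FFT lengths this keeps 32 bins for both modalities at
    4000 Hz: EEG df = 1.25 Hz -> bins up to 40 Hz; EMG df = 15.625 Hz ->
    bins up to 500 Hz.  The lower band edges are enforced by the band-pass
    pre-filtering, not by the crop.
    """

    eeg_band: tuple[float, float] = (0.5, 40.0)
    emg_band: tuple[float, float] = (20.0, 500.0)

    def band(self, modality: str) -> tuple[float, float]:
        return self.eeg_band if modality == "EEG" else self.emg_band

    def bin_slice(self, modality: str, fft_len: int, fs: float) -> slice:
        df = fs / fft_len
        hi = int(np.floor(self.band(modality)[1] / df))
        return slice(1, hi + 1)


@dataclass(frozen=True)
class NormalizationStats:
    """Per-(subject, modality) min/max used for the [0, 1] rescale."""

    subject_id: str
    modality: str
    vmin: float
    vmax: float

    def __post_init__(self) -> None:
        if self.vmax < self.vmin:
            raise ValueError("max must be >= min")


LayoutKind = str  # "vertical" | "depth" | "signal"

#: layout name -> (kind, channel row order)
LAYOUTS: dict[str, tuple[LayoutKind, tuple[str, ...]]] = {
    "grouped": ("vertical", ("C3", "C4", "Cz", "biceps", "triceps")),
    "mixed": ("vertical", ("C3", "biceps", "C4", "triceps", "Cz")),
    "eeg_stack": ("vertical", ("C3", "C4", "Cz")),
    "emg_stack": ("vertical", ("biceps", "triceps")),
    "stacked": ("depth", ("C3", "C4", "Cz", "biceps", "triceps")),
    "eeg_multi": ("depth", ("C3", "C4", "Cz")),
    "emg_multi": ("depth", ("biceps", "triceps")),
    "signal_full": ("signal", ("C3", "C4", "Cz", "biceps", "triceps")),
    "signal_eeg": ("signal", ("C3", "C4", "Cz")),
    "signal_emg": ("signal", ("biceps", "triceps")),
}

SPECTROGRAM_LAYOUTS = tuple(k for k, (kind, _) in LAYOUTS.items()
                            if kind in ("vertical", "depth"))
SIGNAL_LAYOUTS = tuple(k for k, (kind, _) in LAYOUTS.items()
                       if kind == "signal")


def modality_of(channel: str) -> str:
    return "EEG" if channel in CHANNEL_NAMES[:3] else "EMG"


def _frames(x: np.ndarray, win_len: int, hop: int) -> np.ndarray:
    """(..., N) -> (..., F, win_len) frames starting at 0, hop, 2*hop, ..."""
    if x.shape[-1] < win_len:
        raise ValueError(
            f"window of {x.shape[-1]} samples shorter than STFT length {win_len}"
        )
    view = np.lib.stride_tricks.sliding_window_view(x, win_len, axis=-1)
    return view[..., ::hop, :]


def _stft_magnitude(x: np.ndarray, modality: str, spec: StftSpec,
                    crop: CropSpec, fs: float) -> np.ndarray:
    """|STFT| of (..., N) signals -> (..., n_bins, n_frames) images.

    Only the cropped bins are evaluated, via an explicit DFT matrix; this
    is numerically identical to a zero-padded FFT restricted to those bins.
    """
    fft_len = spec.fft_len(modality)
    sl = crop.bin_slice(modality, fft_len, fs)
    frames = _frames(x, spec.win_len, spec.hop) * spec.taper()
    k = np.arange(sl.start, sl.stop)
    n = np.arange(spec.win_len)
    dft = np.exp(-2j * np.pi * np.outer(n, k) / fft_len).astype(np.complex64)
    mag = np.abs(frames.astype(np.float32) @ dft)
    if spec.log_magnitude:
        mag = np.log1p(mag)
    return np.swapaxes(mag, -1, -2)  # rows = frequency, columns = time


def spectrogram(channel_window: np.ndarray, modality: str,
                spec: StftSpec | None = None, crop: CropSpec | None = None,
                fs: float = 4000.0) -> np.ndarray:
    """Cropped magnitude spectrogram of one channel window.

    Returns an (n_bins, n_frames) array -- (32, 68) under the defaults --
    with frequency increasing down the rows and time along the columns.
    """
    spec = spec or StftSpec()
    crop = crop or CropSpec()
    x = np.asarray(channel_window)
    if x.ndim != 1:
        raise ValueError("channel_window must be 1-D")
    return _stft_magnitude(x, modality, spec, crop, fs)


def fit_normalization(values: np.ndarray, subject_id: str,
                      modality: str) -> NormalizationStats:
    """Record the global min/max of a subject+modality value collection."""
    arr = np.asarray(values)
    if arr.size == 0:
        raise ValueError("cannot fit normalization on an empty collection")
    return NormalizationStats(subject_id, modality,
                              float(arr.min()), float(arr.max()))


def apply_normalization(x: np.ndarray, stats: NormalizationStats,
                        subject_id: str | None = None) -> np.ndarray:
    """Affine rescale to [0, 1]; a constant collection maps to all zeros."""
    if subject_id is not None and subject_id != stats.subject_id:
        log.warning("applying %s stats fitted on subject %s to subject %s",
                    stats.modality, stats.subject_id, subject_id)
    span = stats.vmax - stats.vmin
    if span == 0:
        return np.zeros_like(np.asarray(x, dtype=np.float32))
    return ((np.asarray(x) - stats.vmin) / span).astype(np.float32)


def assemble_layout(channel_images: dict[str, np.ndarray],
                    layout: str) -> np.ndarray:
    """Fuse per-channel images into a single CNN input.

    Vertical layouts concatenate along the height axis in the layout's row
    order; depth layouts stack along a trailing channel axis.  Pixel values
    are passed through unchanged.
    """
    kind, order = _layout(layout)
    if kind == "signal":
        raise ValueError("use signal_image() for time-domain layouts")
    missing = [c for c in order if c not in channel_images]
    if missing:
        raise ValueError(f"layout '{layout}' needs channels {missing}")
    imgs = [np.asarray(channel_images[c]) for c in order]
    if len({im.shape for im in imgs}) != 1:
        raise ValueError("channel images must share one shape")
    if kind == "vertical":
        return np.concatenate(imgs, axis=0)
    return np.stack(imgs, axis=-1)


def _layout(layout: str) -> tuple[LayoutKind, tuple[str, ...]]:
    try:
        return LAYOUTS[layout]
    except KeyError:
        raise ValueError(f"unknown layout '{layout}'; one of {sorted(LAYOUTS)}")


def signal_image(window: np.ndarray, stats_eeg: NormalizationStats,
                 stats_emg: NormalizationStats,
                 layout: str = "signal_full") -> np.ndarray:
    """Normalized time-domain image: channels as rows, samples as columns.

    EEG rows are rescaled with the subject's EEG amplitude extrema and EMG
    rows with the EMG extrema, so the two modalities occupy comparable
    [0, 1] ranges within one image.
    """
    kind, order = _layout(layout)
    if kind != "signal":
        raise ValueError(f"'{layout}' is not a signal layout")
    if stats_eeg is None or stats_emg is None:
        raise ValueError("per-modality normalization stats are required")
    w = np.asarray(window)
    if w.ndim != 2 or w.shape[0] != len(CHANNEL_NAMES):
        raise ValueError("window must be a 5 x N array")
    rows = []
    for c in order:
        r = CHANNEL_NAMES.index(c)
        stats = stats_eeg if modality_of(c) == "EEG" else stats_emg
        rows.append(apply_normalization(w[r], stats))
    return np.stack(rows, axis=0)


@dataclass
class ImageDataset:
    """CNN-ready tensors for one subject and one layout.

    ``images`` has shape (W, H, Wd) for single-channel layouts or
    (W, H, Wd, C) for depth-stacked ones; all values lie in [0, 1].
    """

    layout: str
    subject_id: str
    images: np.ndarray
    labels: np.ndarray          # (W,) int weight classes
    weight_label: np.ndarray
    speed_label: np.ndarray
    rep_index: np.ndarray
    trial_index: np.ndarray
    row_order: tuple[str, ...]
    n_classes: int = 3
    stats: dict[str, NormalizationStats] = field(default_factory=dict)

    def __len__(self) -> int:
        return self.images.shape[0]

    @property
    def input_shape(self) -> tuple[int, ...]:
        return self.images.shape[1:]

    def subset(self, idx: np.ndarray) -> "ImageDataset":
        return ImageDataset(
            self.layout, self.subject_id, self.images[idx], self.labels[idx],
            self.weight_label[idx], self.speed_label[idx],
            self.rep_index[idx], self.trial_index[idx], self.row_order,
            self.n_classes, self.stats,
        )


def _raw_spectrograms(ws: WindowSet, spec: StftSpec,
                      crop: CropSpec) -> np.ndarray:
    """(W, 5, n_bins, n_frames) unnormalized magnitudes for all windows."""
    out = []
    for rows, modality in ((EEG_ROWS, "EEG"), (EMG_ROWS, "EMG")):
        x = ws.samples[:, list(rows), :]
        out.append((rows, _stft_magnitude(x, modality, spec, crop,
                                          ws.sampling_rate)))
    shape = out[0][1].shape
    full = np.empty((len(ws), 5, shape[-2], shape[-1]), np.float32)
    for rows, mags in out:
        full[:, list(rows)] = mags
    return full


def build_image_dataset(ws: WindowSet, layout: str,
                        spec: StftSpec | None = None,
                        crop: CropSpec | None = None,
                        stats: dict[str, NormalizationStats] | None = None,
                        fit_indices: np.ndarray | None = None) -> ImageDataset:
    """Convert a WindowSet into a normalized ImageDataset for one layout.

    Normalization extrema are fitted over every window of the subject by
    default, matching the per-subject procedure; pass ``fit_indices`` to
    restrict fitting to (say) the training windows instead -- that mode
    avoids using held-out data in the rescale but deviates from the
    default protocol.
    """
    spec = spec or StftSpec()
    crop = crop or CropSpec()
    kind, order = _layout(layout)
    fit_sel = slice(None) if fit_indices is None else fit_indices

    if kind == "signal":
        source = ws.samples  # normalized amplitudes directly
        per_channel = {c: ws.samples[:, CHANNEL_NAMES.index(c), :]
                       for c in order}
    else:
        raw = _raw_spectrograms(ws, spec, crop)
        source = raw
        per_channel = {c: raw[:, CHANNEL_NAMES.index(c)] for c in order}

    if stats is None:
        stats = {}
        for modality, rows in (("EEG", EEG_ROWS), ("EMG", EMG_ROWS)):
            vals = source[fit_sel][:, list(rows)]
            stats[modality] = fit_normalization(vals, ws.subject_id, modality)

    norm = {c: apply_normalization(img, stats[modality_of(c)], ws.subject_id)
            for c, img in per_channel.items()}

    if kind == "vertical":
        images = np.concatenate([norm[c] for c in order], axis=1)
    elif kind == "depth":
        images = np.stack([norm[c] for c in order], axis=-1)
    else:
        images = np.stack([norm[c] for c in order], axis=1)

    return ImageDataset(
        layout=layout, subject_id=ws.subject_id, images=images,
        labels=ws.weight_class.copy(), weight_label=ws.weight_label.copy(),
        speed_label=ws.speed_label.copy(), rep_index=ws.rep_index.copy(),
        trial_index=ws.trial_index.copy(), row_order=order,
        n_classes=ws.n_classes, stats=dict(stats),
    )
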