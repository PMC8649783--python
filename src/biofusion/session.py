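"""Core containers for a recording session.

A session records elbow flexion-extension under a 2 (speed) x 3 (weight)
full-factorial design: each speed/weight pairing is one *trial*, performed
for several *repetitions*.  Five channels are recorded throughout -- three
EEG electrodes over the motor cortex (C3, C4, Cz per the 10-20 system) and
two EMG electrodes over the biceps and triceps of the moving arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Fixed channel order used everywhere: EEG first, then EMG.
CHANNEL_NAMES: tuple[str, ...] = ("C3", "C4", "Cz", "biceps", "triceps")
EEG_CHANNELS: tuple[str, ...] = ("C3", "C4", "Cz")
EMG_CHANNELS: tuple[str, ...] = ("biceps", "triceps")
#: Row indices of each modality within the 5-channel sample array.
EEG_ROWS: tuple[int, ...] = (0, 1, 2)
EMG_ROWS: tuple[int, ...] = (3, 4)

#: Load levels (lbs) mapped to integer class labels.
WEIGHT_CLASSES: dict[float, int] = {0.0: 0, 3.0: 1, 5.0: 2}


@dataclass(frozen=True)
class SessionSpec:
    """Factorial layout and timing of one subject's session.

    Defaults mirror the study protocol: two self-paced speeds (slow
    ~10 deg/s -> ~30 s per repetition; fast ~150 deg/s -> ~2 s), three
    task weights (0/3/5 lbs), three repetitions per trial, a 3 s pause
    between repetitions, all sampled at 4000 Hz.
    """

    subject_id: str = "S01"
    sampling_rate: float = 4000.0
    slow_duration: float = 30.0
    fast_duration: float = 2.0
    weights: tuple[float, ...] = (0.0, 3.0, 5.0)
    reps_per_trial: int = 3
    inter_rep_pause: float = 3.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 2 * 500.0:
            raise ValueError(
                "sampling_rate must exceed twice the 500 Hz EMG band edge"
            )
        if self.slow_duration <= 0 or self.fast_duration <= 0:
            raise ValueError("repetition durations must be positive")
        if self.reps_per_trial < 1:
            raise ValueError("reps_per_trial must be >= 1")
        if list(self.weights) != sorted(set(self.weights)):
            raise ValueError("weights must be strictly increasing")

    @property
    def speeds(self) -> tuple[tuple[str, float], ...]:
        """(label, repetition duration in s) for each speed level."""
        return (("slow", self.slow_duration), ("fast", self.fast_duration))


@dataclass(frozen=True)
class EffectModel:
    """Controllable generative effects linking task conditions to signals.

    ``emg_gain_per_lb``
        Multiplicative amplitude gain of active-muscle EMG per lb of load.
    ``eeg_erd_depth_per_lb``
        Fractional reduction of mu/beta band power per lb during movement
        (event-related desynchronization).
    ``speed_gain``
        Extra EMG amplitude factor applied to fast repetitions.
    ``noise_sd``
        Baseline additive broadband noise level, relative to the EEG
        background amplitude.
    ``artifact_rate``
        Expected motion-artifact transients per second (on all channels).
    ``emg_fatigue_spectral_shift``
        Optional downward shift of the EMG carrier band, in Hz per
        repetition (0 disables the hook).
    """

    emg_gain_per_lb: float = 0.15
    eeg_erd_depth_per_lb: float = 0.05
    speed_gain: float = 1.3
    noise_sd: float = 0.1
    artifact_rate: float = 0.1
    emg_fatigue_spectral_shift: float = 0.0

    def __post_init__(self) -> None:
        if min(self.emg_gain_per_lb, self.eeg_erd_depth_per_lb,
               self.speed_gain, self.noise_sd, self.artifact_rate) < 0:
            raise ValueError("effect gains must be non-negative")

    def validate_for(self, spec: SessionSpec) -> None:
        """Reject ERD depths that would drive band power negative."""
        max_w = max(spec.weights)
        if self.eeg_erd_depth_per_lb * max_w >= 1.0:
            raise ValueError(
                "eeg_erd_depth_per_lb * max weight must stay below 1 "
                "(band power would become non-positive)"
            )


@dataclass
class Repetition:
    """One repetition: a 5 x N sample array (mV) plus movement markers.

    ``start_marker``/``end_marker`` bracket the movement portion of the
    recording (half-open, 0-based sample indices).
    """

    samples: np.ndarray  # (5, N) float32, mV
    start_marker: int
    end_marker: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(CHANNEL_NAMES):
            raise ValueError("samples must be a 5 x N array")
        n = self.samples.shape[1]
        if not (0 <= self.start_marker < self.end_marker <= n):
            raise ValueError(
                f"markers ({self.start_marker}, {self.end_marker}) invalid "
                f"for length {n}"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class Trial:
    """One speed/weight pairing with its repetitions."""

    speed_label: str
    weight_label: float
    reps: list[Repetition] = field(default_factory=list)

    @property
    def weight_class(self) -> int:
        return WEIGHT_CLASSES[float(self.weight_label)]


@dataclass
class Recording:
    """A subject's full session: |speeds| x |weights| trials."""

    subject_id: str
    sampling_rate: float
    trials: list[Trial] = field(default_factory=list)
    channel_names: tuple[str, ...] = CHANNEL_NAMES

    def __post_init__(self) -> None:
        if tuple(self.channel_names) != CHANNEL_NAMES:
            raise ValueError(f"channel order must be {CHANNEL_NAMES}")

    def map_samples(self, fn) -> "Recording":
        """Return a copy with ``fn(samples) -> samples`` applied per rep."""
        trials = []
        for t in self.trials:
            reps = [Repetition(fn(r.samples), r.start_marker, r.end_marker)
                    for r in t.reps]
            trials.append(Trial(t.speed_label, t.weight_label, reps))
        return replace(self, trials=trials)
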