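"""Compact, fully seeded end-to-end experiments.

:func:`quick_fusion_experiment` runs the whole pipeline at a reduced scale
on one synthetic subject: a short hyperparameter search for the grouped
EEG+EMG spectrogram model, then single-modality baselines trained with the
hyperparameters the search selected.  It exists so that examples, smoke
checks and reports all exercise the identical code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import evaluation, imaging, models, preprocess, synth
from .session import SessionSpec


@dataclass
class QuickResult:
    """Outcome of :func:`quick_fusion_experiment`."""

    subject_id: str
    best_hyperparams: dict
    accuracy_pct: dict[str, float]      # layout -> test accuracy (%)
    n_test: dict[str, int]              # layout -> test-set size
    chance_pct: float
    search_log: pd.DataFrame = field(repr=False, default=None)


def quick_fusion_experiment(
    seed: int = 1,
    subject_id: str = "S01",
    slow_duration: float = 8.0,
    fast_duration: float = 2.0,
    fusion_layout: str = "grouped",
    baseline_layouts: tuple[str, ...] = ("emg_stack", "eeg_stack"),
) -> QuickResult:
    """One-subject fusion-versus-single-modality experiment.

    The session is shortened (slow repetitions default to 8 s instead of
    30 s) so the whole experiment runs in minutes on one CPU.  The fused
    layout gets a 5-trial random search over the reduced space with at most
    15 epochs per fit; each baseline layout reuses the selected
    hyperparameters for a single fit, making the comparison about the
    input representation rather than the tuning budget.
    """
    spec = SessionSpec(subject_id=subject_id, rng_seed=seed,
                       slow_duration=slow_duration,
                       fast_duration=fast_duration)
    rec = preprocess.segment_movement(
        preprocess.filter_recording(synth.generate_recording(spec)))
    ws = preprocess.make_windows(rec)

    tspec = models.TrainSpec.quick(rng_seed=seed)
    space = models.SearchSpace.quick()
    split_spec = evaluation.SplitSpec(shuffle_seed=seed)

    def dataset_splits(layout):
        ds = imaging.build_image_dataset(ws, layout)
        sp = evaluation.split_windows(ds, split_spec)
        return ds.subset(sp.train), ds.subset(sp.val), ds.subset(sp.test)

    train_ds, val_ds, test_ds = dataset_splits(fusion_layout)
    chance = 100.0 / train_ds.n_classes
    result = models.tune(train_ds, val_ds, "spectro2d", space, tspec)
    report = evaluation.evaluate(result.best_model, test_ds,
                                 model_name=fusion_layout)
    accuracy = {fusion_layout: report.accuracy_pct}
    n_test = {fusion_layout: report.n_test}

    for layout in baseline_layouts:
        tr, va, te = dataset_splits(layout)
        model = models.train_model(tr, va, "spectro2d",
                                   result.best_hyperparams, tspec, seed=seed)
        rep = evaluation.evaluate(model, te, model_name=layout)
        accuracy[layout] = rep.accuracy_pct
        n_test[layout] = rep.n_test

    return QuickResult(
        subject_id=subject_id,
        best_hyperparams=result.best_hyperparams,
        accuracy_pct=accuracy,
        n_test=n_test,
        chance_pct=chance,
        search_log=result.log,
    )
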