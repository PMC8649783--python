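"""Configuration-driven orchestration of the full pipeline.

``run()`` executes generate -> filter -> segment -> window -> image ->
tune/train -> evaluate for every requested (layout, family) pairing and
subject, then writes a run directory with the comparison table, per-subject
reports and all seeds/configs needed to reproduce the run.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import evaluation, imaging, models, preprocess, synth
from .session import EffectModel, SessionSpec

log = logging.getLogger(__name__)

#: families admissible for each input layout
COMPATIBLE_FAMILIES: dict[str, tuple[str, ...]] = {
    **{k: ("spectro2d",) for k in imaging.SPECTROGRAM_LAYOUTS},
    **{k: ("split_conv", "conv1d") for k in imaging.SIGNAL_LAYOUTS},
}


class Pairing(BaseModel):
    model_config = ConfigDict(extra="forbid")
    layout: str
    family: str
    name: str = ""

    @field_validator("layout")
    @classmethod
    def _known_layout(cls, v):
        if v not in imaging.LAYOUTS:
            raise ValueError(f"unknown layout '{v}'")
        return v

    def validate_pairing(self) -> "Pairing":
        if self.family not in models.FAMILIES:
            raise ValueError(f"unknown family '{self.family}'")
        if self.family not in COMPATIBLE_FAMILIES[self.layout]:
            raise ValueError(
                f"family '{self.family}' incompatible with layout "
                f"'{self.layout}' (allowed: {COMPATIBLE_FAMILIES[self.layout]})")
        if not self.name:
            self.name = f"{self.layout}:{self.family}"
        return self


class RunConfig(BaseModel):
    """Schema-validated run configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    out_dir: str = "runs/run"
    seed: int = 0
    subjects: list[str] = Field(default_factory=lambda: ["S01"])
    quick: bool = False
    session: dict = Field(default_factory=dict)   # SessionSpec overrides
    effects: dict = Field(default_factory=dict)   # EffectModel overrides
    filters: dict = Field(default_factory=dict)   # FilterSpec overrides
    stft: dict = Field(default_factory=dict)      # StftSpec overrides
    split: dict = Field(default_factory=dict)     # SplitSpec overrides
    train: dict = Field(default_factory=dict)     # TrainSpec overrides
    pairings: list[Pairing] = Field(default_factory=lambda: [
        Pairing(layout="grouped", family="spectro2d")])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))


def subject_dataset(config: RunConfig, subject: str, layout: str
                    ) -> imaging.ImageDataset:
    """Generate and preprocess one subject, returning a layout's images."""
    spec = SessionSpec(subject_id=subject, rng_seed=config.seed,
                       **config.session)
    effects = EffectModel(**config.effects)
    rec = synth.generate_recording(spec, effects)
    rec = preprocess.filter_recording(
        rec, preprocess.FilterSpec(**config.filters))
    rec = preprocess.segment_movement(rec)
    ws = preprocess.make_windows(rec)
    return imaging.build_image_dataset(
        ws, layout, spec=imaging.StftSpec(**config.stft))


def _subject_seed(global_seed: int, subject: str, pairing: str) -> int:
    return int(np.random.SeedSequence(
        [global_seed, zlib.crc32(subject.encode()),
         zlib.crc32(pairing.encode())]).generate_state(1)[0] % (2 ** 31))


def run(config: RunConfig) -> Path:
    """Execute the configured pipeline; returns the run directory."""
    for p in config.pairings:
        p.validate_pairing()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.model_dump_json(indent=2))

    tspec_base = (models.TrainSpec.quick() if config.quick
                  else models.TrainSpec())
    space = (models.SearchSpace.quick() if config.quick
             else models.SearchSpace())

    per_model: dict[str, list[evaluation.SubjectReport]] = {}
    acc_rows = []
    for subject in config.subjects:
        for pairing in config.pairings:
            stage = f"{subject}/{pairing.name}"
            try:
                log.info("building images: %s", stage)
                ds = subject_dataset(config, subject, pairing.layout)
                split = evaluation.split_windows(
                    ds, evaluation.SplitSpec(shuffle_seed=config.seed,
                                             **config.split))
                train_ds = ds.subset(split.train)
                val_ds = ds.subset(split.val)
                test_ds = ds.subset(split.test)
                seed = _subject_seed(config.seed, subject, pairing.name)
                tspec = models.TrainSpec(**{
                    **asdict(tspec_base), "rng_seed": seed, **config.train})
                log.info("tuning %s (%d trials x %d fits)", stage,
                         tspec.search_trials, tspec.trainings_per_trial)
                result = models.tune(train_ds, val_ds, pairing.family,
                                     space, tspec)
                model_dir = out / subject / pairing.name.replace(":", "_")
                models.save_run(result.best_model, model_dir, result.log)
                report = evaluation.evaluate(result.best_model, test_ds,
                                             model_name=pairing.name)
                per_model.setdefault(pairing.name, []).append(report)
                acc_rows.append({
                    "subject": subject, "model": pairing.name,
                    "accuracy_pct": report.accuracy_pct,
                    **{f"accuracy_{k}_pct": v
                       for k, v in report.speed_accuracy_pct.items()},
                    "macro_f_pct": report.macro_f_pct,
                    "n_test": report.n_test,
                })
            except Exception as exc:  # noqa: BLE001 - annotate failing stage
                raise RuntimeError(f"pipeline stage failed at {stage}") from exc

    acc_table = pd.DataFrame(acc_rows)
    acc_table.to_csv(out / "subject_accuracy.csv", index=False)

    summary: dict = {"models": {}}
    for name, reports in per_model.items():
        agg = evaluation.aggregate(reports)
        summary["models"][name] = {
            "mean_accuracy_pct": agg.mean_accuracy_pct,
            "sd_accuracy_pct": agg.sd_accuracy_pct,
            "pooled_f_pct": agg.pooled_f_pct,
            "mean_macro_f_pct": agg.mean_macro_f_pct,
            "n_subjects": agg.n_subjects,
        }
        np.savetxt(out / f"confusion_{name.replace(':', '_')}.csv",
                   agg.pooled_confusion, fmt="%d", delimiter=",")

    if len(per_model) >= 2 and len(config.subjects) >= 2:
        wide = acc_table.pivot(index="subject", columns="model",
                               values="accuracy_pct")
        cmp_res = evaluation.compare_models(wide)
        summary["anova"] = {
            "f_statistic": cmp_res.f_statistic, "p_value": cmp_res.p_value,
            "df": [cmp_res.df_models, cmp_res.df_error],
            "pairwise_p": json.loads(cmp_res.pairwise_p.to_json()),
        }

    (out / "report.json").write_text(json.dumps(summary, indent=2))
    log.info("run complete: %s", out)
    return out
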