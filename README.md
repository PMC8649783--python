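# biofusion

CNN-based **input-level fusion of EEG and EMG** for classifying the task
weight (0, 3 or 5 lbs) held during elbow flexion–extension.

Three EEG channels (C3, C4, Cz) and two EMG channels (biceps, triceps),
sampled at 4000 Hz, are filtered, segmented at movement markers and cut
into 250 ms windows with 50% overlap.  Each window/channel becomes a
32 × 68 short-time Fourier magnitude image (56-sample Hann window, 75%
overlap; EEG cropped to 1.25–40 Hz, EMG to 15.6–500 Hz), normalized to
[0, 1] per subject and modality.  The five channel images are fused *at
the input*: stacked vertically with modalities grouped or interleaved,
or along image depth — plus single-modality and raw-signal baselines.
Small CNNs are tuned by random search and evaluated subject-by-subject
(train on repetitions 1–2, validate/test on a stratified split of
repetition 3), and models are compared across subjects with a
repeated-measures ANOVA and Bonferroni-adjusted paired t-tests.

Real recordings are not distributed; a seeded synthetic generator
produces sessions with the relevant structure (load-dependent EMG
amplitude, EEG event-related desynchronization, 1/f background, motion
artifacts).  See [`docs/methods.md`](docs/methods.md) for models,
parameters and limitations.  The CNNs run on the package's own NumPy
training engine (`biofusion.nn`) — no GPU or deep-learning framework
required.

## Worked example

```python
import biofusion as bf
from biofusion import evaluation, models

spec = bf.SessionSpec(subject_id="DEMO", rng_seed=0,
                      slow_duration=4.0, fast_duration=2.0)
rec = bf.segment_movement(bf.filter_recording(
    bf.generate_recording(spec, bf.EffectModel())))
ds = bf.build_image_dataset(bf.make_windows(rec), "grouped")  # 160x68 images
split = bf.split_windows(ds, bf.SplitSpec(shuffle_seed=0))

hp = {"kernels": [3, 3, 3], "filters": [8, 8, 8],
      "dropout_conv": [0.0, 0.0, 0.0], "units": [40, 40],
      "dropout_fc": [0.0, 0.0], "adam_lr": 1e-3}
model = models.train_model(ds.subset(split.train), ds.subset(split.val),
                           "spectro2d", hp,
                           models.TrainSpec(max_epochs=10), seed=0)
print(evaluation.evaluate(model, ds.subset(split.test)).accuracy_pct)
```

Running this (it is `examples/04_train_quick_model.py`) prints:

```
stopped after epoch 10 (best epoch 10)
test accuracy 50.7% on 69 windows (chance 33.3%)
confusion matrix (rows true 0/3/5 lbs, cols predicted):
     18   5   0
      8   7   8
      1  12  10
```

— a deliberately tiny model on a short session, already well above the
33.3% chance level.  The other scripts in [`examples/`](examples/) walk
through each capability: session simulation, preprocessing/windowing,
fusion image construction, the fusion-vs-single-modality experiment and
the cross-model statistics.

## Command line

```sh
biofusion simulate --subject S01 --seed 0 --out rec.h5
biofusion preprocess --recording rec.h5 --out windows.h5
biofusion images --windows windows.h5 --layout grouped --out images.h5
biofusion tune --images images.h5 --family spectro2d --quick --out run/
biofusion evaluate --run-dir run/ --images images.h5
biofusion run-all --config config.yaml        # full multi-subject pipeline
```

`run-all` reads a YAML `RunConfig` (schema-validated; unknown keys are
rejected) and writes a run directory with per-subject models,
`subject_accuracy.csv`, pooled confusion matrices and `report.json`
including the ANOVA when at least two models and two subjects are run.

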