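"""Train one small CNN on grouped fusion images and score it on held-out data.

Repetitions 0-1 train the model; repetition 2 is shuffled and split 50/50
into validation (early stopping) and test (reported).  Runs in well under
a minute on one CPU thanks to the deliberately small configuration.
"""

import biofusion as bf
from biofusion import evaluation, models

spec = bf.SessionSpec(subject_id="DEMO", rng_seed=0,
                      slow_duration=4.0, fast_duration=2.0)
rec = bf.segment_movement(bf.filter_recording(
    bf.generate_recording(spec, bf.EffectModel())))
ds = bf.build_image_dataset(bf.make_windows(rec), "grouped")
split = bf.split_windows(ds, bf.SplitSpec(shuffle_seed=0))

hp = {"kernels": [3, 3, 3], "filters": [8, 8, 8],
      "dropout_conv": [0.0, 0.0, 0.0], "units": [40, 40],
      "dropout_fc": [0.0, 0.0], "adam_lr": 1e-3}
model = models.train_model(ds.subset(split.train), ds.subset(split.val),
                           "spectro2d", hp,
                           models.TrainSpec(max_epochs=10), seed=0)
report = evaluation.evaluate(model, ds.subset(split.test))

print(f"stopped after epoch {model.history.stopped_epoch} "
      f"(best epoch {model.history.best_epoch})")
print(f"test accuracy {report.accuracy_pct:.1f}% on {report.n_test} windows "
      f"(chance 33.3%)")
print("confusion matrix (rows true 0/3/5 lbs, cols predicted):")
for row in report.confusion.astype(int):
    print("   ", " ".join(f"{v:3d}" for v in row))
print("-> even a tiny CNN on a short session separates the three task "
      "weights above chance.")
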