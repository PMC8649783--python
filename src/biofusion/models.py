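"""CNN families, hyperparameter search space, and the training protocol.

Three base architectures classify task weight from the image inputs:

``spectro2d``
    Three [conv2d -> 2x2 max-pool -> dropout] blocks, then two dense+dropout
    layers and a 3-way softmax.  Fed with vertically fused spectrograms
    (height x width x 1) or depth-stacked ones (32 x 68 x C); for the
    multi-channel inputs all kernels are fixed at 3x3 so the tensors cannot
    shrink below the minimum feasible size.
``split_conv``
    A factored first stage common in EEG decoding: a temporal 1 x k kernel
    followed by a spatial (height x 1) kernel, then 1x2 max-pool, dropout
    and the same dense head.  Fed with 5 x 1000 signal images.
``conv1d``
    Three [conv1d -> pool-2 -> dropout] blocks over the 1000-sample,
    5-channel sequence, then the dense head.

Hyperparameters are tuned by random search: 50 sampled configurations,
each trained twice, scored by validation loss; training uses Adam,
categorical cross-entropy, batch size 32, an epoch limit of 50 and early
stopping with patience 5 on validation loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import ImageDataset
from .nn import Conv2D, Dense, Dropout, Flatten, MaxPool2D, ReLU, Sequential
from .nn.network import History

FAMILIES = ("spectro2d", "split_conv", "conv1d")


@dataclass(frozen=True)
class SearchSpace:
    """Tunable hyperparameters and their admissible values.

    Defaults reproduce the full tuning grid: 2-D kernels 3x3/5x5 (7x7
    additionally allowed in the third convolution layer), 1-D kernel widths
    3..55 step 2, filter counts 8..1024 in powers of two (capped at 512 for
    split_conv), dropout 0..0.5 step 0.05, dense units 20..500 step 20 and
    a log-uniform Adam learning rate on [1e-5, 1e-2].
    """

    kernel_sizes_2d: tuple[int, ...] = (3, 5)
    kernel_sizes_2d_third: tuple[int, ...] = (3, 5, 7)
    kernel_widths_1d: tuple[int, ...] = tuple(range(3, 56, 2))
    filters: tuple[int, ...] = (8, 16, 32, 64, 128, 256, 512, 1024)
    split_conv_max_filters: int = 512
    dropouts: tuple[float, ...] = tuple(round(0.05 * i, 2) for i in range(11))
    dense_units: tuple[int, ...] = tuple(range(20, 501, 20))
    lr_log10_range: tuple[float, float] = (-5.0, -2.0)

    @classmethod
    def quick(cls) -> "SearchSpace":
        """A reduced space for smoke runs and CI-scale experiments."""
        return cls(
            kernel_sizes_2d=(3,),
            kernel_sizes_2d_third=(3,),
            kernel_widths_1d=(5, 9, 15),
            filters=(8, 16),
            split_conv_max_filters=16,
            dropouts=(0.0, 0.1, 0.2),
            dense_units=(20, 40, 60),
            lr_log10_range=(-3.5, -2.5),
        )


@dataclass(frozen=True)
class TrainSpec:
    """Fixed training protocol settings."""

    batch_size: int = 32
    max_epochs: int = 50
    early_stop_patience: int = 5
    search_trials: int = 50
    trainings_per_trial: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.max_epochs, self.early_stop_patience,
               self.search_trials, self.trainings_per_trial) < 1:
            raise ValueError("all training settings must be positive")

    @classmethod
    def quick(cls, rng_seed: int = 0) -> "TrainSpec":
        return cls(max_epochs=15, search_trials=5, trainings_per_trial=1,
                   rng_seed=rng_seed)


@dataclass
class ShapeChain:
    """Result of propagating an input shape through a configuration."""

    feasible: bool
    layers: list[tuple[str, tuple[int, ...]]]
    reason: str = ""


def _is_multichannel(family: str, input_shape: tuple[int, ...]) -> bool:
    return family == "spectro2d" and len(input_shape) == 3 and input_shape[-1] > 1


def propagate_shapes(family: str, input_shape: tuple[int, ...],
                     hyperparams: dict) -> ShapeChain:
    """Valid-padding conv/pool shape arithmetic for a configuration.

    Convolution with valid padding maps n -> n - k + 1 per spatial axis and
    pooling maps n -> floor(n / p); any dimension below 1 marks the
    configuration infeasible (used by the sampler to resample).
    """
    hp = hyperparams
    chain: list[tuple[str, tuple[int, ...]]] = []

    def conv(h, w, kh, kw, f, name):
        ho, wo = h - kh + 1, w - kw + 1
        chain.append((name, (ho, wo, f)))
        return ho, wo

    def pool(h, w, ph, pw, f, name):
        ho, wo = h // ph, w // pw
        chain.append((name, (ho, wo, f)))
        return ho, wo

    def bad(i=None):
        where = chain[-1] if chain else ("input", input_shape)
        return ShapeChain(False, chain, f"dimension < 1 at {where[0]}")

    if family == "spectro2d":
        h, w = input_shape[:2]
        for i in range(3):
            k = hp["kernels"][i]
            h, w = conv(h, w, k, k, hp["filters"][i], f"conv{i + 1}")
            if h < 1 or w < 1:
                return bad()
            h, w = pool(h, w, 2, 2, hp["filters"][i], f"pool{i + 1}")
            if h < 1 or w < 1:
                return bad()
        flat = h * w * hp["filters"][2]
    elif family == "split_conv":
        h, w = input_shape[:2]
        kw = hp["kernel_width"]
        h, w = conv(h, w, 1, kw, hp["filters"][0], "conv_temporal")
        if w < 1:
            return bad()
        h, w = conv(h, w, h, 1, hp["filters"][1], "conv_spatial")
        h, w = pool(h, w, 1, 2, hp["filters"][1], "pool1")
        if w < 1:
            return bad()
        flat = h * w * hp["filters"][1]
    elif family == "conv1d":
        length = input_shape[0] if len(input_shape) == 2 else input_shape[1]
        for i in range(3):
            length = length - hp["kernels"][i] + 1
            chain.append((f"conv{i + 1}", (length, hp["filters"][i])))
            if length < 1:
                return bad()
            length //= 2
            chain.append((f"pool{i + 1}", (length, hp["filters"][i])))
            if length < 1:
                return bad()
        flat = length * hp["filters"][2]
    else:
        raise ValueError(f"unknown family '{family}'")

    chain.append(("flatten", (flat,)))
    for i, u in enumerate(hp["units"]):
        chain.append((f"dense{i + 1}", (u,)))
    chain.append(("output", (3,)))
    return ShapeChain(True, chain)


def sample_config(space: SearchSpace, family: str,
                  input_shape: tuple[int, ...],
                  rng: np.random.Generator,
                  max_retries: int = 100) -> dict:
    """Draw one hyperparameter assignment, resampling infeasible shapes.

    Every tunable slot is drawn independently; for multi-channel
    spectrogram inputs the 2-D kernel size is pinned to 3x3.
    """
    multi = _is_multichannel(family, input_shape)
    for _ in range(max_retries):
        hp: dict = {}
        if family == "spectro2d":
            if multi:
                hp["kernels"] = [3, 3, 3]
            else:
                hp["kernels"] = [
                    int(rng.choice(space.kernel_sizes_2d)),
                    int(rng.choice(space.kernel_sizes_2d)),
                    int(rng.choice(space.kernel_sizes_2d_third)),
                ]
            hp["filters"] = [int(rng.choice(space.filters)) for _ in range(3)]
            hp["dropout_conv"] = [float(rng.choice(space.dropouts))
                                  for _ in range(3)]
        elif family == "split_conv":
            filt = [f for f in space.filters
                    if f <= space.split_conv_max_filters]
            hp["kernel_width"] = int(rng.choice(space.kernel_widths_1d))
            hp["filters"] = [int(rng.choice(filt)) for _ in range(2)]
            hp["dropout_conv"] = [float(rng.choice(space.dropouts))]
        elif family == "conv1d":
            hp["kernels"] = [int(rng.choice(space.kernel_widths_1d))
                             for _ in range(3)]
            hp["filters"] = [int(rng.choice(space.filters)) for _ in range(3)]
            hp["dropout_conv"] = [float(rng.choice(space.dropouts))
                                  for _ in range(3)]
        else:
            raise ValueError(f"unknown family '{family}'")
        hp["units"] = [int(rng.choice(space.dense_units)) for _ in range(2)]
        hp["dropout_fc"] = [float(rng.choice(space.dropouts)) for _ in range(2)]
        lo, hi = space.lr_log10_range
        hp["adam_lr"] = float(10 ** rng.uniform(lo, hi))
        if propagate_shapes(family, input_shape, hp).feasible:
            return hp
    raise RuntimeError(
        f"no feasible configuration found for {family} with input "
        f"{input_shape} after {max_retries} draws")


def to_model_input(images: np.ndarray, family: str) -> np.ndarray:
    """Orient an ImageDataset tensor for a family's input convention."""
    if family == "spectro2d":
        return images[..., None] if images.ndim == 3 else images
    if family == "split_conv":
        return images[..., None]  # (N, H, L, 1)
    if family == "conv1d":
        return np.swapaxes(images, 1, 2)[:, None, :, :]  # (N, 1, L, C)
    raise ValueError(f"unknown family '{family}'")


def model_input_shape(images: np.ndarray, family: str) -> tuple[int, ...]:
    return to_model_input(images[:1], family).shape[1:]


def build_model(family: str, input_shape: tuple[int, ...], hyperparams: dict,
                n_classes: int = 3, seed: int = 0) -> Sequential:
    """Instantiate a seeded network for one family + hyperparameter set.

    ``input_shape`` is the oriented per-sample shape (see
    :func:`to_model_input`).
    """
    hp = hyperparams
    drop_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    layers: list = []
    if family == "spectro2d":
        for i in range(3):
            k = hp["kernels"][i]
            layers += [Conv2D(k, k, hp["filters"][i]), ReLU(),
                       MaxPool2D(2, 2), Dropout(hp["dropout_conv"][i], drop_rng)]
    elif family == "split_conv":
        h = input_shape[0]
        layers += [Conv2D(1, hp["kernel_width"], hp["filters"][0]), ReLU(),
                   Conv2D(h, 1, hp["filters"][1]), ReLU(),
                   MaxPool2D(1, 2), Dropout(hp["dropout_conv"][0], drop_rng)]
    elif family == "conv1d":
        for i in range(3):
            layers += [Conv2D(1, hp["kernels"][i], hp["filters"][i]), ReLU(),
                       MaxPool2D(1, 2), Dropout(hp["dropout_conv"][i], drop_rng)]
    else:
        raise ValueError(f"unknown family '{family}'")
    layers.append(Flatten())
    for i in range(2):
        layers += [Dense(hp["units"][i]), ReLU(),
                   Dropout(hp["dropout_fc"][i], drop_rng)]
    layers.append(Dense(n_classes, init="glorot"))
    return Sequential(layers, input_shape, n_classes, seed=seed)


@dataclass
class TrainedModel:
    """A fitted network plus its provenance."""

    family: str
    layout: str
    hyperparams: dict
    net: Sequential
    history: History

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(to_model_input(images, self.family))

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.net.predict(to_model_input(images, self.family))


def _as_xy(ds) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(ds, ImageDataset):
        return ds.images, ds.labels
    x, y = ds
    return np.asarray(x), np.asarray(y)


def train_model(train, val, family: str, hyperparams: dict,
                tspec: TrainSpec | None = None, seed: int = 0,
                layout: str = "") -> TrainedModel:
    """Fit one configuration with the fixed protocol.

    ``train``/``val`` are :class:`~biofusion.imaging.ImageDataset` splits or
    ``(images, labels)`` tuples.  Training runs Adam on categorical
    cross-entropy with batch size 32, stopping early once validation loss
    has not improved for the patience window and restoring the best-epoch
    weights.
    """
    tspec = tspec or TrainSpec()
    xt, yt = _as_xy(train)
    xv, yv = _as_xy(val)
    if isinstance(train, ImageDataset) and not layout:
        layout = train.layout
    xt = to_model_input(xt, family)
    xv = to_model_input(xv, family)
    net = build_model(family, xt.shape[1:], hyperparams, seed=seed)
    hist = net.fit(xt, yt, xv, yv,
                   epochs=tspec.max_epochs, batch_size=tspec.batch_size,
                   lr=hyperparams["adam_lr"],
                   patience=tspec.early_stop_patience, seed=seed)
    return TrainedModel(family, layout, dict(hyperparams), net, hist)


@dataclass
class TuneResult:
    best_hyperparams: dict
    best_score: float
    best_model: TrainedModel
    log: pd.DataFrame  # one row per fit: trial, repeat, val_loss, ...


def tune(train, val, family: str, space: SearchSpace | None = None,
         tspec: TrainSpec | None = None,
         input_shape: tuple[int, ...] | None = None) -> TuneResult:
    """Random-search hyperparameter tuning.

    Samples ``tspec.search_trials`` configurations, fits each
    ``tspec.trainings_per_trial`` times, scores a configuration by the
    minimum validation loss over its repeats, and returns the argmin
    configuration with a log of every fit.
    """
    space = space or SearchSpace()
    tspec = tspec or TrainSpec()
    xt, _ = _as_xy(train)
    shape = input_shape or model_input_shape(xt, family)
    rng = np.random.default_rng(np.random.SeedSequence([tspec.rng_seed, 2]))

    rows = []
    best_score = np.inf
    best_hp: dict | None = None
    best_model: TrainedModel | None = None
    for trial in range(tspec.search_trials):
        hp = sample_config(space, family, shape, rng)
        fit_scores = []
        for repeat in range(tspec.trainings_per_trial):
            seed = int(rng.integers(2 ** 31))
            model = train_model(train, val, family, hp, tspec, seed=seed)
            vl = model.history.val_loss[model.history.best_epoch - 1]
            va = model.history.val_accuracy[model.history.best_epoch - 1]
            fit_scores.append((vl, model))
            rows.append({
                "trial": trial, "repeat": repeat, "seed": seed,
                "val_loss": vl, "val_accuracy": va,
                "epochs": model.history.stopped_epoch,
                "config": json.dumps(hp),
            })
        score = min(s for s, _ in fit_scores)
        if score < best_score:
            best_score = score
            best_hp = hp
            best_model = min(fit_scores, key=lambda t: t[0])[1]

    return TuneResult(best_hp, float(best_score), best_model,
                      pd.DataFrame(rows))


def save_run(model: TrainedModel, out_dir: str | Path,
             search_log: pd.DataFrame | None = None) -> Path:
    """Persist a fitted model: config.json, history.csv, weights.npz."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(
        {"family": model.family, "layout": model.layout,
         "input_shape": list(model.net.input_shape),
         "hyperparams": model.hyperparams}, indent=2))
    h = model.history
    pd.DataFrame({
        "epoch": np.arange(1, len(h.loss) + 1),
        "loss": h.loss, "accuracy": h.accuracy,
        "val_loss": h.val_loss or np.nan,
        "val_accuracy": h.val_accuracy or np.nan,
    }).to_csv(out / "history.csv", index=False)
    weights = {f"layer{i}_{k}": v
               for i, layer in enumerate(model.net.layers)
               for k, v in layer.params.items()}
    np.savez(out / "weights.npz", **weights)
    if search_log is not None:
        search_log.to_csv(out / "search_log.csv", index=False)
    return out


def load_run(run_dir: str | Path) -> TrainedModel:
    """Rebuild a saved model (architecture + weights) from a run directory."""
    run_dir = Path(run_dir)
    cfg = json.loads((run_dir / "config.json").read_text())
    net = build_model(cfg["family"], tuple(cfg["input_shape"]),
                      cfg["hyperparams"])
    with np.load(run_dir / "weights.npz") as weights:
        for key, value in weights.items():
            layer_id, name = key.split("_", 1)
            net.layers[int(layer_id[5:])].params[name][...] = value
    return TrainedModel(cfg["family"], cfg.get("layout", ""),
                        cfg["hyperparams"], net, History())
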