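"""Sequential model with softmax cross-entropy head, Adam and early stopping."""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .layers import Layer


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _one_hot(y: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((len(y), k), np.float32)
    out[np.arange(len(y)), y] = 1.0
    return out


@dataclass
class History:
    """Per-epoch training record."""

    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0
    monitor: str = "val_loss"


class _Adam:
    """Adaptive moment estimation (beta1 0.9, beta2 0.999, eps 1e-7)."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7) -> None:
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[int, np.ndarray] = {}
        self.v: dict[int, np.ndarray] = {}

    def step(self, layers: list[Layer]) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for li, layer in enumerate(layers):
            for name, p in layer.params.items():
                g = layer.grads[name]
                key = (li, name)
                m = self.m.setdefault(key, np.zeros_like(p))
                v = self.v.setdefault(key, np.zeros_like(p))
                m += (1 - self.b1) * (g - m)
                v += (1 - self.b2) * (g * g - v)
                p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class Sequential:
    """A feed-forward stack of layers trained with softmax cross-entropy.

    ``input_shape`` is the per-sample shape (channels last); the final layer
    must produce the class logits.
    """

    def __init__(self, layers: list[Layer], input_shape: tuple[int, ...],
                 n_classes: int, seed: int = 0) -> None:
        self.layers = layers
        self.input_shape = tuple(input_shape)
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)
        shape = self.input_shape
        for layer in layers:
            shape = layer.build(shape, rng)
        if shape != (n_classes,):
            raise ValueError(
                f"network output shape {shape} != ({n_classes},)")

    # -- inference ---------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def activation_shapes(self, batch: int = 2) -> list[tuple[int, ...]]:
        """Per-layer realized output shapes on a dummy batch (sans batch dim)."""
        x = np.zeros((batch,) + self.input_shape, np.float32)
        shapes = []
        for layer in self.layers:
            x = layer.forward(x, train=False)
            shapes.append(x.shape[1:])
        return shapes

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = [softmax(self.forward(x[i:i + batch_size].astype(np.float32)))
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        # np.argmax breaks ties toward the lowest class index
        return np.argmax(self.predict_proba(x, batch_size), axis=1)

    def evaluate(self, x: np.ndarray, y: np.ndarray,
                 batch_size: int = 256) -> tuple[float, float]:
        """(cross-entropy loss, accuracy) over a labeled set."""
        p = self.predict_proba(x, batch_size)
        eps = 1e-12
        loss = float(-np.mean(np.log(p[np.arange(len(y)), y] + eps)))
        acc = float(np.mean(p.argmax(axis=1) == y))
        return loss, acc

    # -- training ----------------------------------------------------------

    def _snapshot(self) -> list[dict[str, np.ndarray]]:
        return [copy.deepcopy(layer.params) for layer in self.layers]

    def _restore(self, snap: list[dict[str, np.ndarray]]) -> None:
        for layer, params in zip(self.layers, snap):
            for k, v in params.items():
                layer.params[k][...] = v

    def fit(self, x: np.ndarray, y: np.ndarray,
            x_val: np.ndarray | None = None, y_val: np.ndarray | None = None,
            epochs: int = 50, batch_size: int = 32, lr: float = 1e-3,
            patience: int = 5, seed: int = 0,
            restore_best: bool = True) -> History:
        """Minibatch Adam training with validation-loss early stopping.

        Stops after ``patience`` epochs without a new best validation loss
        (or at ``epochs``), restoring the best-epoch weights by default.
        """
        if len(np.unique(y)) < 2:
            raise ValueError("training split contains a single class")
        x = x.astype(np.float32)
        y = np.asarray(y)
        y1h = _one_hot(y, self.n_classes)
        rng = np.random.default_rng(seed)
        opt = _Adam(lr)
        hist = History()
        best = np.inf
        best_snap = self._snapshot()
        wait = 0
        monitor_val = x_val is not None and y_val is not None

        for epoch in range(1, epochs + 1):
            order = rng.permutation(len(x))
            losses, hits, seen = [], 0, 0
            for start in range(0, len(x), batch_size):
                idx = order[start:start + batch_size]
                xb, yb = x[idx], y1h[idx]
                logits = self.forward(xb, train=True)
                p = softmax(logits)
                eps = 1e-12
                losses.append(float(-np.mean(
                    np.log((p * yb).sum(axis=1) + eps))))
                hits += int((p.argmax(axis=1) == y[idx]).sum())
                seen += len(idx)
                grad = (p - yb) / len(idx)
                for layer in reversed(self.layers):
                    grad = layer.backward(grad)
                opt.step(self.layers)

            hist.loss.append(float(np.mean(losses)))
            hist.accuracy.append(hits / seen)
            if monitor_val:
                vl, va = self.evaluate(x_val, y_val)
                hist.val_loss.append(vl)
                hist.val_accuracy.append(va)
                current = vl
            else:
                current = hist.loss[-1]
                hist.monitor = "loss"

            hist.stopped_epoch = epoch
            if current < best - 1e-12:
                best = current
                hist.best_epoch = epoch
                best_snap = self._snapshot()
                wait = 0
            else:
                wait += 1
                if wait >= patience:
                    break

        if restore_best:
            self._restore(best_snap)
        return hist
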