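"""Layers: forward/backward pairs over channels-last float32 tensors.

Every layer exposes ``forward(x, train)`` and ``backward(dout)``;
parameterized layers keep ``params`` and matching ``grads`` dictionaries
that the optimizer walks.  Convolution uses valid padding and unit stride;
pooling uses equal size and stride with floor truncation -- the only
variants the architectures require.
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def build(self, in_shape: tuple[int, ...], rng: np.random.Generator
              ) -> tuple[int, ...]:
        """Allocate parameters for ``in_shape`` (per-sample); return out shape."""
        return self.out_shape(in_shape)

    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        raise NotImplementedError

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Valid 2-D convolution, stride 1x1, channels-last.

    Kernel (kh, kw, C, F); He-normal initialization suited to the ReLU
    that follows each convolution.
    """

    def __init__(self, kh: int, kw: int, filters: int) -> None:
        super().__init__()
        if min(kh, kw, filters) < 1:
            raise ValueError("kernel dims and filter count must be >= 1")
        self.kh, self.kw, self.filters = kh, kw, filters

    def out_shape(self, in_shape):
        h, w, _ = in_shape
        ho, wo = h - self.kh + 1, w - self.kw + 1
        if ho < 1 or wo < 1:
            raise ValueError(
                f"kernel {self.kh}x{self.kw} larger than input {h}x{w}")
        return (ho, wo, self.filters)

    def build(self, in_shape, rng):
        c = in_shape[-1]
        fan_in = self.kh * self.kw * c
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in),
            size=(self.kh, self.kw, c, self.filters)).astype(np.float32)
        self.params["b"] = np.zeros(self.filters, np.float32)
        return self.out_shape(in_shape)

    def forward(self, x, train=False):
        w, b = self.params["W"], self.params["b"]
        n, h, wd, c = x.shape
        ho, wo = h - self.kh + 1, wd - self.kw + 1
        # im2col via kernel-offset slices: one large GEMM per batch
        col = np.empty((n, ho, wo, self.kh * self.kw, c), x.dtype)
        for i in range(self.kh):
            for j in range(self.kw):
                col[:, :, :, i * self.kw + j, :] = x[:, i:i + ho, j:j + wo, :]
        self._col = col.reshape(n * ho * wo, self.kh * self.kw * c)
        self._dims = (n, h, wd, c, ho, wo)
        out = self._col @ w.reshape(-1, self.filters) + b
        return out.reshape(n, ho, wo, self.filters)

    def backward(self, dout):
        w = self.params["W"]
        n, h, wd, c, ho, wo = self._dims
        dflat = dout.reshape(n * ho * wo, self.filters)
        self.grads["W"] = (self._col.T @ dflat).reshape(w.shape)
        self.grads["b"] = dflat.sum(axis=0)
        dcol = (dflat @ w.reshape(-1, self.filters).T).reshape(
            n, ho, wo, self.kh, self.kw, c)
        dx = np.zeros((n, h, wd, c), dout.dtype)
        for i in range(self.kh):
            for j in range(self.kw):
                dx[:, i:i + ho, j:j + wo, :] += dcol[:, :, :, i, j, :]
        return dx


class MaxPool2D(Layer):
    """Max pooling with size == stride; trailing remainder rows/cols dropped."""

    def __init__(self, ph: int, pw: int) -> None:
        super().__init__()
        self.ph, self.pw = ph, pw

    def out_shape(self, in_shape):
        h, w, c = in_shape
        ho, wo = h // self.ph, w // self.pw
        if ho < 1 or wo < 1:
            raise ValueError(f"pool {self.ph}x{self.pw} larger than input {h}x{w}")
        return (ho, wo, c)

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        ph, pw = self.ph, self.pw
        ho, wo = h // ph, w // pw
        self._in_shape = x.shape
        xc = x[:, :ho * ph, :wo * pw, :]
        out = np.full((n, ho, wo, c), -np.inf, x.dtype)
        arg = np.zeros((n, ho, wo, c), np.uint8)
        # streaming max over the pool offsets; first occurrence wins ties
        for idx in range(ph * pw):
            i, j = divmod(idx, pw)
            s = xc[:, i::ph, j::pw, :]
            m = s > out
            np.copyto(out, s, where=m)
            arg[m] = idx
        self._arg = arg
        return out

    def backward(self, dout):
        n, h, w, c = self._in_shape
        ph, pw = self.ph, self.pw
        ho, wo = h // ph, w // pw
        dx = np.zeros((n, h, w, c), dout.dtype)
        for idx in range(ph * pw):
            i, j = divmod(idx, pw)
            dx[:, i:ho * ph:ph, j:wo * pw:pw, :] += dout * (self._arg == idx)
        return dx


class ReLU(Layer):
    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class Dropout(Layer):
    """Inverted dropout; identity at p == 0 or at inference time."""

    def __init__(self, p: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not (0.0 <= p < 1.0):
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng()

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return (x * self._mask).astype(x.dtype)

    def backward(self, dout):
        if self._mask is None:
            return dout
        return (dout * self._mask).astype(dout.dtype)


class Flatten(Layer):
    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer; He init (hidden) or Glorot init (output)."""

    def __init__(self, units: int, init: str = "he") -> None:
        super().__init__()
        if units < 1:
            raise ValueError("units must be >= 1")
        self.units = units
        self.init = init

    def out_shape(self, in_shape):
        return (self.units,)

    def build(self, in_shape, rng):
        (d,) = in_shape
        if self.init == "he":
            std = np.sqrt(2.0 / d)
        else:
            std = np.sqrt(2.0 / (d + self.units))
        self.params["W"] = rng.normal(0.0, std, size=(d, self.units)).astype(np.float32)
        self.params["b"] = np.zeros(self.units, np.float32)
        return (self.units,)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T
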