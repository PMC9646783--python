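"""Minimal CPU convolutional-network engine.

Implements exactly the pieces the tile classifier needs — 3x3 same-padding
convolutions (im2col), ReLU, 2x2 max pooling, global average pooling, a dense
head, Adam, and a weighted binary cross-entropy on logits — with full
backpropagation. Intermediate activations and their gradients are retained by
name so class-activation maps can be computed from any convolutional layer.

Arrays are channels-last ``(N, H, W, C)``; parameters default to float32.
All randomness is injected through ``numpy.random.Generator`` instances, so a
fixed seed reproduces initial weights and training bit-for-bit on one CPU.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
    "Adam",
    "sigmoid",
    "weighted_bce_with_logits",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def weighted_bce_with_logits(z, y, w):
    """Per-class-weighted binary cross-entropy on logits.

    Returns ``(loss, dz)`` where ``loss = mean_i w_i * BCE(sigmoid(z_i), y_i)``
    (mean over the batch, keras-style) and ``dz`` is its gradient. With unit
    weights this is the standard binary cross-entropy.
    """
    z = np.asarray(z, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    w = np.asarray(w, dtype=np.float64).ravel()
    n = z.size
    # softplus(z) - y*z is BCE expressed on the logit scale (stable)
    loss = float(np.mean(w * (np.logaddexp(0.0, z) - y * z)))
    dz = w * (sigmoid(z) - y) / n
    return loss, dz


class Layer:
    """Base layer: named, optionally trainable, with a params/grads dict."""

    def __init__(self, name: str):
        self.name = name
        self.trainable = True
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    @property
    def has_params(self) -> bool:
        return bool(self.params)

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray, need_dx: bool = True):  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Patch matrix of a same-padded input: (N*H*W, k*k*C), patch order
    (row, col, channel)."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # N,H,W,C,k,k
    n, h, w = x.shape[:3]
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        n * h * w, k * k * x.shape[3]
    )


class Conv2D(Layer):
    """3x3 (or kxk, odd) convolution, stride 1, same padding."""

    def __init__(self, name, c_in, c_out, *, kernel=3, rng=None, dtype=np.float32):
        super().__init__(name)
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng(0)
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        fan_in = kernel * kernel * c_in
        scale = np.sqrt(2.0 / fan_in)  # He initialisation
        self.params = {
            "W": (rng.standard_normal((fan_in, c_out)) * scale).astype(dtype),
            "b": np.zeros(c_out, dtype=dtype),
        }
        self._cols = None
        self._shape = None

    def forward(self, x):
        x = np.asarray(x, dtype=self.params["W"].dtype)
        self._shape = x.shape
        self._cols = _im2col(x, self.kernel)
        n, h, w, _ = x.shape
        out = self._cols @ self.params["W"] + self.params["b"]
        return out.reshape(n, h, w, self.c_out)

    def backward(self, dout, need_dx=True):
        n, h, w, _ = self._shape
        dflat = np.ascontiguousarray(dout, dtype=self.params["W"].dtype).reshape(
            -1, self.c_out
        )
        self.grads = {"W": self._cols.T @ dflat, "b": dflat.sum(axis=0)}
        if not need_dx:
            return None
        k = self.kernel
        # dx = convolution of dout with the 180-degree-rotated kernels,
        # input/output channels swapped — one more im2col matmul.
        w4 = self.params["W"].reshape(k, k, self.c_in, self.c_out)
        w_flip = np.ascontiguousarray(w4[::-1, ::-1].transpose(0, 1, 3, 2)).reshape(
            k * k * self.c_out, self.c_in
        )
        cols = _im2col(dflat.reshape(n, h, w, self.c_out), k)
        return (cols @ w_flip).reshape(n, h, w, self.c_in)


class ReLU(Layer):
    def __init__(self, name):
        super().__init__(name)
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout, need_dx=True):
        return dout * self._mask if need_dx else None


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; ties route the gradient to the first max."""

    def __init__(self, name):
        super().__init__(name)
        self._argmax = None
        self._shape = None

    def forward(self, x):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"{self.name}: spatial dims must be even, got {h}x{w}")
        self._shape = x.shape
        win = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        win = win.reshape(n, h // 2, w // 2, c, 4)
        self._argmax = win.argmax(axis=-1)
        return np.take_along_axis(win, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout, need_dx=True):
        if not need_dx:
            return None
        n, h, w, c = self._shape
        win = np.zeros((n, h // 2, w // 2, c, 4), dtype=dout.dtype)
        np.put_along_axis(win, self._argmax[..., None], dout[..., None], axis=-1)
        win = win.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return win.reshape(n, h, w, c)


class GlobalAvgPool(Layer):
    def __init__(self, name):
        super().__init__(name)
        self._shape = None

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout, need_dx=True):
        if not need_dx:
            return None
        n, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :] / (h * w), (n, h, w, c)).copy()


class Dense(Layer):
    def __init__(self, name, c_in, c_out, *, rng=None, dtype=np.float32):
        super().__init__(name)
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / c_in)
        self.params = {
            "W": (rng.standard_normal((c_in, c_out)) * scale).astype(dtype),
            "b": np.zeros(c_out, dtype=dtype),
        }
        self._x = None

    def forward(self, x):
        self._x = np.asarray(x, dtype=self.params["W"].dtype)
        return self._x @ self.params["W"] + self.params["b"]

    def backward(self, dout, need_dx=True):
        dout = np.asarray(dout, dtype=self.params["W"].dtype)
        self.grads = {"W": self._x.T @ dout, "b": dout.sum(axis=0)}
        return dout @ self.params["W"].T if need_dx else None


class Sequential:
    """A plain layer stack with named activations and gradient capture."""

    def __init__(self, layers: Sequence[Layer]):
        names = [l.name for l in layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        self.layers = list(layers)
        self._acts: dict[str, np.ndarray] = {}
        self._act_grads: dict[str, np.ndarray] = {}

    def __getitem__(self, name: str) -> Layer:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)

    @property
    def layer_names(self) -> list[str]:
        return [l.name for l in self.layers]

    def forward(self, x: np.ndarray, *, keep_activations: bool = False) -> np.ndarray:
        self._acts = {}
        for l in self.layers:
            x = l.forward(x)
            if keep_activations:
                self._acts[l.name] = x
        return x

    def activation(self, name: str) -> np.ndarray:
        return self._acts[name]

    def activation_gradient(self, name: str) -> np.ndarray:
        return self._act_grads[name]

    def backward(self, dout: np.ndarray, *, capture: str | None = None) -> None:
        """Backpropagate ``dout`` (gradient w.r.t. the final output).

        Stops as soon as every trainable parameterised layer below has been
        served, unless ``capture`` names a deeper layer whose output gradient
        is wanted (stored, retrievable via :meth:`activation_gradient`).
        """
        self._act_grads = {}
        stop = 0
        trainable_idx = [
            i for i, l in enumerate(self.layers) if l.has_params and l.trainable
        ]
        if trainable_idx:
            stop = min(trainable_idx)
        if capture is not None:
            stop = min(stop, self.layers.index(self[capture]))
        for i in range(len(self.layers) - 1, -1, -1):
            l = self.layers[i]
            if capture is not None and l.name == capture:
                # dout here is the gradient w.r.t. this layer's *output*
                self._act_grads[l.name] = np.asarray(dout).copy()
            need_dx = i > stop
            dout = l.backward(dout, need_dx=need_dx)
            if not need_dx:
                break

    # -- weight snapshots ---------------------------------------------------
    def get_weights(self) -> list[dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in l.params.items()} for l in self.layers]

    def set_weights(self, weights: list[dict[str, np.ndarray]]) -> None:
        for l, w in zip(self.layers, weights, strict=True):
            for k in l.params:
                l.params[k] = w[k].copy()

    # -- serialisation ------------------------------------------------------
    def save(self, path) -> None:
        arrays = {}
        meta = []
        for l in self.layers:
            meta.append({"name": l.name, "type": type(l).__name__})
            for k, v in l.params.items():
                arrays[f"{l.name}/{k}"] = v
        np.savez(path, __meta__=json.dumps(meta), **arrays)

    def load_weights(self, path) -> None:
        with np.load(path, allow_pickle=False) as data:
            for l in self.layers:
                for k in l.params:
                    l.params[k] = np.asarray(data[f"{l.name}/{k}"])


class Adam:
    """Adam over the trainable parameters of a :class:`Sequential` model."""

    def __init__(self, model: Sequential, lr: float, beta1=0.9, beta2=0.999, eps=1e-7):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[tuple[str, str], np.ndarray] = {}
        self._v: dict[tuple[str, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for l in self.model.layers:
            if not (l.has_params and l.trainable):
                continue
            for k, g in l.grads.items():
                key = (l.name, k)
                if key not in self._m:
                    self._m[key] = np.zeros_like(l.params[k])
                    self._v[key] = np.zeros_like(l.params[k])
                m = self._m[key]
                v = self._v[key]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * np.square(g)
                update = (self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)).astype(
                    l.params[k].dtype
                )
                l.params[k] -= update
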