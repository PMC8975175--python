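"""Minimal numpy layer stack with manual gradients.

Only what the Q-network needs: 1-D convolutions (standard and
depthwise-separable), dense layers, ReLU, and Adam.  Everything is float64
and driven by explicit ``numpy.random.Generator`` seeding, so training runs
are bit-reproducible on a machine.

Shapes: convolution inputs are ``(batch, channels, width)``; 'same' zero
padding keeps the width fixed through the trunk.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np


class Layer:
    """Base: ``params``/``grads`` are dicts of arrays keyed per layer."""

    def __init__(self) -> None:
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def _windows(xp: np.ndarray, k: int) -> np.ndarray:
    """(B, C, Wp) -> (B, C, W, k) sliding windows (view)."""
    return np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)


def _pad_same(x: np.ndarray, k: int) -> np.ndarray:
    lo = (k - 1) // 2
    hi = k - 1 - lo
    return np.pad(x, ((0, 0), (0, 0), (lo, hi)))


class Conv1d(Layer):
    """Standard 1-D convolution, 'same' padding, stride 1."""

    def __init__(self, c_in: int, c_out: int, k: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.params["W"] = _he_init(rng, (c_out, c_in, k), c_in * k)
        self.params["b"] = np.zeros(c_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        win = _windows(_pad_same(x, self.k), self.k)  # (B,C,W,k)
        self._win = win
        out = np.einsum("bcwt,oct->bow", win, self.params["W"],
                        optimize=True)
        return out + self.params["b"][None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = np.einsum("bcwt,bow->oct", self._win, dout,
                                    optimize=True)
        self.grads["b"] = dout.sum(axis=(0, 2))
        B, _, W = self._x.shape
        lo = (self.k - 1) // 2
        dxp = np.zeros((B, self.c_in, W + self.k - 1))
        contrib = np.einsum("bow,oct->bcwt", dout, self.params["W"],
                            optimize=True)
        for t in range(self.k):
            dxp[:, :, t:t + W] += contrib[:, :, :, t]
        return dxp[:, :, lo:lo + W] if self.k > 1 else dxp


class DepthwiseConv1d(Layer):
    """Per-channel 1-D convolution (the depthwise half of separable conv)."""

    def __init__(self, c: int, k: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.c, self.k = c, k
        self.params["W"] = _he_init(rng, (c, k), k)
        self.params["b"] = np.zeros(c)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        win = _windows(_pad_same(x, self.k), self.k)  # (B,C,W,k)
        self._win = win
        out = np.einsum("bcwt,ct->bcw", win, self.params["W"], optimize=True)
        return out + self.params["b"][None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = np.einsum("bcwt,bcw->ct", self._win, dout,
                                    optimize=True)
        self.grads["b"] = dout.sum(axis=(0, 2))
        B, _, W = self._x.shape
        lo = (self.k - 1) // 2
        dxp = np.zeros((B, self.c, W + self.k - 1))
        contrib = np.einsum("bcw,ct->bcwt", dout, self.params["W"],
                            optimize=True)
        for t in range(self.k):
            dxp[:, :, t:t + W] += contrib[:, :, :, t]
        return dxp[:, :, lo:lo + W] if self.k > 1 else dxp


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = _he_init(rng, (n_in, n_out), n_in)
        self.params["b"] = np.zeros(n_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


def parameter_vector(layers: List[Layer]) -> Dict[str, np.ndarray]:
    """Flat name->array mapping over a layer list (views, not copies)."""
    out: Dict[str, np.ndarray] = {}
    for i, layer in enumerate(layers):
        for name, arr in layer.params.items():
            out[f"{i}:{type(layer).__name__}:{name}"] = arr
    return out


def n_parameters(layers: List[Layer]) -> int:
    return sum(arr.size for arr in parameter_vector(layers).values())


class Adam:
    """Adam with global gradient-norm clipping."""

    def __init__(self, layers: List[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, clip_norm: float = 10.0) -> None:
        self.layers = layers
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = {k: np.zeros_like(v)
                  for k, v in parameter_vector(layers).items()}
        self.v = {k: np.zeros_like(v)
                  for k, v in parameter_vector(layers).items()}

    def step(self) -> None:
        self.t += 1
        params = parameter_vector(self.layers)
        grads = {}
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                grads[f"{i}:{type(layer).__name__}:{name}"] = layer.grads[name]
        total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
        scale = min(1.0, self.clip_norm / total) if total > 0 else 1.0
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for key, p in params.items():
            g = grads[key] * scale
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
            p -= self.lr * (self.m[key] / b1t) / (
                np.sqrt(self.v[key] / b2t) + self.eps)
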