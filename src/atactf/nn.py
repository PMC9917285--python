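"""Minimal 1-D convolutional network engine (numpy, hand-written backprop).

Implements exactly the layer zoo the TFBS model needs: same-padded dilated
1-D convolution, ReLU, batch normalization, width-w max pooling, and a
binary-cross-entropy-with-logits loss, plus Glorot initialization and the
Adam optimizer. Tensors are (batch, channels, length) float32.

Convolutions are computed as K slice-matmuls (one per kernel tap), which is
fast in numpy for the small kernel widths used here and keeps the backward
pass exact and simple.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np


class Layer:
    """Base layer: forward caches what backward needs."""

    params: Dict[str, np.ndarray]
    grads: Dict[str, np.ndarray]

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """Same-padded, stride-1, dilated 1-D convolution.

    Output length equals input length; padding is dilation*(k-1)/2 per side
    (kernel width must be odd).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 dilation: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel width must be odd for symmetric same padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.dilation = dilation
        self.pad = dilation * (kernel - 1) // 2
        rng = rng or np.random.default_rng()
        # Glorot (Xavier) uniform
        fan_in = in_channels * kernel
        fan_out = out_channels * kernel
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.params["W"] = rng.uniform(
            -limit, limit, size=(out_channels, in_channels, kernel)
        ).astype(np.float32)
        self.params["b"] = np.zeros(out_channels, dtype=np.float32)
        self.grads["W"] = np.zeros_like(self.params["W"])
        self.grads["b"] = np.zeros_like(self.params["b"])
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, length = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        w, b = self.params["W"], self.params["b"]
        # im2col: one large GEMM (out_ch, c*k) @ (c*k, n*length)
        cols = np.empty((c, self.kernel, n, length), dtype=np.float32)
        for k in range(self.kernel):
            off = k * self.dilation
            cols[:, k] = xp[:, :, off:off + length].transpose(1, 0, 2)
        cols2 = cols.reshape(c * self.kernel, n * length)
        out2 = w.reshape(self.out_channels, -1) @ cols2
        out2 += b[:, None]
        out = out2.reshape(self.out_channels, n, length).transpose(1, 0, 2)
        if training:
            self._cols2 = cols2
            self._in_shape = (n, c, length)
        return np.ascontiguousarray(out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, _, length = dy.shape
        _, c, _ = self._in_shape
        w = self.params["W"]
        dy2 = np.ascontiguousarray(dy.transpose(1, 0, 2)).reshape(
            self.out_channels, n * length
        )
        self.grads["W"][:] = (dy2 @ self._cols2.T).reshape(w.shape)
        self.grads["b"][:] = dy2.sum(axis=1)
        dcols = (w.reshape(self.out_channels, -1).T @ dy2).reshape(
            c, self.kernel, n, length
        )
        dxp = np.zeros((n, c, length + 2 * self.pad), dtype=np.float32)
        for k in range(self.kernel):
            off = k * self.dilation
            dxp[:, :, off:off + length] += dcols[:, k].transpose(1, 0, 2)
        self._cols2 = None
        if self.pad:
            return dxp[:, :, self.pad:-self.pad]
        return dxp


class ReLU(Layer):
    def forward(self, x, training):
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, dy):
        return dy * self._mask


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.grads["gamma"] = np.zeros(channels, dtype=np.float32)
        self.grads["beta"] = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        out = self.params["gamma"][None, :, None] * xhat + self.params["beta"][None, :, None]
        if training:
            self._xhat = xhat
            self._inv = inv
        return out

    def backward(self, dy):
        xhat, inv = self._xhat, self._inv
        n, _, length = dy.shape
        m = n * length
        self.grads["gamma"][:] = (dy * xhat).sum(axis=(0, 2))
        self.grads["beta"][:] = dy.sum(axis=(0, 2))
        g = self.params["gamma"]
        dxhat = dy * g[None, :, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True) / m
        ) * inv[None, :, None]
        return dx.astype(np.float32)


class MaxPool1d(Layer):
    """Non-overlapping max pooling of width w (length must divide by w)."""

    def __init__(self, width: int = 2):
        super().__init__()
        self.width = width

    def forward(self, x, training):
        n, c, length = x.shape
        if length % self.width:
            raise ValueError(f"length {length} not divisible by pool width {self.width}")
        xr = x.reshape(n, c, length // self.width, self.width)
        idx = xr.argmax(axis=3)
        out = np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]
        if training:
            self._idx = idx
            self._shape = x.shape
        return out

    def backward(self, dy):
        n, c, lo = dy.shape
        dxr = np.zeros((n, c, lo, self.width), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=3)
        return dxr.reshape(self._shape)


class Sequential:
    def __init__(self, layers: List[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def parameters(self) -> List[Tuple[Layer, str]]:
        return [(layer, name) for layer in self.layers for name in layer.params]

    def state_arrays(self) -> Dict[str, np.ndarray]:
        """Flat name -> array mapping of all parameters and running stats."""
        state = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                state[f"{i}.{name}"] = arr
            if isinstance(layer, BatchNorm1d):
                state[f"{i}.running_mean"] = layer.running_mean
                state[f"{i}.running_var"] = layer.running_var
        return state

    def load_state(self, state: Dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name][:] = state[f"{i}.{name}"]
            if isinstance(layer, BatchNorm1d):
                layer.running_mean = state[f"{i}.running_mean"].copy()
                layer.running_var = state[f"{i}.running_var"].copy()

    def copy_state(self) -> Dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_arrays().items()}


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy from logits; returns (loss, dloss/dlogits)."""
    z = logits
    t = targets
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    grad = (sigmoid(z) - t) / z.size
    return float(loss.mean()), grad.astype(np.float32)


class Adam:
    """Adam optimizer over a Sequential's parameters."""

    def __init__(self, net: Sequential, lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {id(l): {n: np.zeros_like(p) for n, p in l.params.items()}
                  for l in net.layers if l.params}
        self.v = {id(l): {n: np.zeros_like(p) for n, p in l.params.items()}
                  for l in net.layers if l.params}

    def step(self):
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for layer in self.net.layers:
            for name, p in layer.params.items():
                g = layer.grads[name]
                m = self.m[id(layer)][name]
                v = self.v[id(layer)][name]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
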