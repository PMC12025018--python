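"""Minimal 1-D neural-network engine on NumPy.

No deep-learning framework is assumed at runtime, so the handful of layer
types the detection models need — batch norm, strided 1-D convolution with
'same' padding, max pooling, dropout, dense — are implemented here with
explicit forward/backward passes and an Adam optimizer.  Exact analytic
gradients also back the Grad-CAM explanations.

Tensors are ``(batch, channels, length)`` for convolutional layers and
``(batch, features)`` after :class:`Flatten`.  Everything runs in float64 so
gradient checks against finite differences are meaningful.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Layer", "BatchNorm1d", "Conv1d", "ReLU", "MaxPool1d", "Flatten",
    "Dropout", "Dense", "Softmax", "Sequential", "Adam",
    "softmax_cross_entropy", "conv_output_length", "pool_output_length",
]


def conv_output_length(n_in: int, kernel: int, stride: int, padding: str) -> int:
    """Output length of a 1-D convolution; 'same' follows the ceil(n/stride) rule."""
    if padding == "same":
        return -(-n_in // stride)
    if padding == "valid":
        if n_in < kernel:
            raise ValueError(f"input of length {n_in} shorter than kernel {kernel} under 'valid' padding")
        return (n_in - kernel) // stride + 1
    raise ValueError(f"unknown padding {padding!r}")


def pool_output_length(n_in: int, size: int = 2, stride: int = 2) -> int:
    return (n_in - size) // stride + 1


class Layer:
    """Base layer; subclasses cache whatever backward() needs during forward()."""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.g_gamma = np.zeros_like(self.gamma)
        self.g_beta = np.zeros_like(self.beta)

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.g_gamma, "beta": self.g_beta}

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
        self._cache = (xhat, inv_std, training)
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, gout):
        xhat, inv_std, training = self._cache
        self.g_gamma = (gout * xhat).sum(axis=(0, 2))
        self.g_beta = gout.sum(axis=(0, 2))
        gxhat = gout * self.gamma[None, :, None]
        if not training:
            return gxhat * inv_std[None, :, None]
        m = xhat.shape[0] * xhat.shape[2]
        term = gxhat - gxhat.mean(axis=(0, 2), keepdims=True) \
            - xhat * (gxhat * xhat).sum(axis=(0, 2), keepdims=True) / m
        return term * inv_std[None, :, None]


class Conv1d(Layer):
    """1-D convolution (cross-correlation) with 'same' or 'valid' padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: str = "same",
                 rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng(0)
        scale = math.sqrt(2.0 / (in_channels * kernel))
        self.W = rng.normal(0.0, scale, size=(out_channels, in_channels, kernel))
        self.b = np.zeros(out_channels)
        self.stride = stride
        self.padding = padding
        self.kernel = kernel
        self.g_W = np.zeros_like(self.W)
        self.g_b = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.g_W, "b": self.g_b}

    def _pad_amounts(self, n_in: int) -> tuple[int, int, int]:
        n_out = conv_output_length(n_in, self.kernel, self.stride, self.padding)
        if self.padding == "same":
            total = max((n_out - 1) * self.stride + self.kernel - n_in, 0)
            return n_out, total // 2, total - total // 2
        return n_out, 0, 0

    def forward(self, x, training=False):
        n, c, n_in = x.shape
        f, c_w, k = self.W.shape
        if c != c_w:
            raise ValueError(f"expected {c_w} input channels, got {c}")
        n_out, pad_l, pad_r = self._pad_amounts(n_in)
        xp = np.pad(x, ((0, 0), (0, 0), (pad_l, pad_r)))
        s0, s1, s2 = xp.strides
        col = np.lib.stride_tricks.as_strided(
            xp, shape=(n, c, n_out, k), strides=(s0, s1, s2 * self.stride, s2)
        )
        col2 = np.ascontiguousarray(col.transpose(0, 2, 1, 3)).reshape(n * n_out, c * k)
        out = col2 @ self.W.reshape(f, c * k).T + self.b
        self._cache = (col2, x.shape, (n_out, pad_l, pad_r))
        return out.reshape(n, n_out, f).transpose(0, 2, 1)

    def backward(self, gout):
        col2, (n, c, n_in), (n_out, pad_l, pad_r) = self._cache
        f = self.W.shape[0]
        k = self.kernel
        g2 = np.ascontiguousarray(gout.transpose(0, 2, 1)).reshape(n * n_out, f)
        self.g_W = (g2.T @ col2).reshape(self.W.shape)
        self.g_b = g2.sum(axis=0)
        gcol = (g2 @ self.W.reshape(f, c * k)).reshape(n, n_out, c, k).transpose(0, 2, 1, 3)
        gx = np.zeros((n, c, n_in + pad_l + pad_r))
        for j in range(k):
            gx[:, :, j : j + self.stride * n_out : self.stride] += gcol[:, :, :, j]
        return gx[:, :, pad_l : pad_l + n_in]


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        return gout * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling (size == stride); trailing remainder dropped."""

    def __init__(self, size: int = 2) -> None:
        self.size = size

    def forward(self, x, training=False):
        n, c, n_in = x.shape
        n_out = n_in // self.size
        x2 = x[:, :, : n_out * self.size].reshape(n, c, n_out, self.size)
        self._argmax = x2.argmax(axis=3)
        self._in_shape = x.shape
        return x2.max(axis=3)

    def backward(self, gout):
        n, c, n_in = self._in_shape
        n_out = gout.shape[2]
        gx2 = np.zeros((n, c, n_out, self.size))
        np.put_along_axis(gx2, self._argmax[..., None], gout[..., None], axis=3)
        gx = np.zeros((n, c, n_in))
        gx[:, :, : n_out * self.size] = gx2.reshape(n, c, n_out * self.size)
        return gx


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout):
        return gout.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout: active only in training, identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must lie in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, gout):
        return gout if self._mask is None else gout * self._mask


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, math.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.g_W = np.zeros_like(self.W)
        self.g_b = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.g_W, "b": self.g_b}

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, gout):
        self.g_W = self._x.T @ gout
        self.g_b = gout.sum(axis=0)
        return gout @ self.W.T


class Softmax(Layer):
    def forward(self, x, training=False):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=-1, keepdims=True)
        return self._p

    def backward(self, gout):
        p = self._p
        return p * (gout - (gout * p).sum(axis=-1, keepdims=True))


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of integer labels against logits, and d(loss)/d(logits)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    n = logits.shape[0]
    loss = -logp[np.arange(n), labels].mean()
    grad = np.exp(logp)
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


class Sequential:
    """Plain layer stack with hooks to read/backprop intermediate activations."""

    def __init__(self, layers: Sequence[Layer]) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray, training: bool = False, upto: int | None = None) -> np.ndarray:
        stop = len(self.layers) if upto is None else upto
        for layer in self.layers[:stop]:
            x = layer.forward(x, training=training)
        return x

    def forward_collect(self, x: np.ndarray, training: bool = False) -> list[np.ndarray]:
        """Forward pass returning every layer's output (index i = layers[i] output)."""
        acts = []
        for layer in self.layers:
            x = layer.forward(x, training=training)
            acts.append(x)
        return acts

    def backward(self, grad: np.ndarray, start: int | None = None, stop: int = -1) -> np.ndarray:
        """Backprop ``grad`` from layer ``start`` down to (excluding) layer ``stop``."""
        if start is None:
            start = len(self.layers) - 1
        for i in range(start, stop, -1):
            grad = self.layers[i].backward(grad)
        return grad

    def predict(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        """Class predictions (argmax of the final output) in evaluation mode."""
        outs = [self.forward(x[i : i + batch]) for i in range(0, x.shape[0], batch)]
        return np.concatenate(outs).argmax(axis=-1)

    def parameters(self) -> list[tuple[str, Layer, str, np.ndarray]]:
        out = []
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params().items():
                out.append((f"layer{i}.{name}", layer, name, arr))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {key: arr.copy() for key, _, _, arr in self.parameters()}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm1d):
                state[f"layer{i}.running_mean"] = layer.running_mean.copy()
                state[f"layer{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, layer, name, arr in self.parameters():
            arr[...] = state[key]
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm1d):
                layer.running_mean[...] = state[f"layer{i}.running_mean"]
                layer.running_var[...] = state[f"layer{i}.running_var"]

    def checksum(self) -> float:
        """Order-stable parameter checksum used by the freezing tests."""
        return float(sum(np.abs(arr).sum() for _, _, _, arr in self.parameters()))


class Adam:
    """Adam over an explicit (layer, param-name) list so freezing is trivial."""

    def __init__(self, params: Iterable[tuple[str, Layer, str, np.ndarray]],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.entries = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {key: np.zeros_like(arr) for key, _, _, arr in self.entries}
        self.v = {key: np.zeros_like(arr) for key, _, _, arr in self.entries}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, layer, name, arr in self.entries:
            g = layer.grads()[name]
            m = self.m[key] = b1 * self.m[key] + (1 - b1) * g
            v = self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            arr -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
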