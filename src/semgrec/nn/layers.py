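"""Feed-forward building blocks: linear, 1-D convolution, batch norm, pooling.

Conventions: batches lead every shape; convolutional tensors are
(batch, channels, length); weights are initialised fan-in uniform
U(-1/sqrt(fan_in), 1/sqrt(fan_in)) from a caller-supplied Generator so model
construction is seed-deterministic.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Param", "Layer", "Linear", "ReLU", "Conv1d", "BatchNorm1d",
           "MaxPool1d", "Flatten", "Reshape", "Frame", "Transpose", "Dropout",
           "Sequential"]


class Param:
    """A learnable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


def _fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Layer:
    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


class Linear(Layer):
    """Affine map on the trailing axis; arbitrary leading axes."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.in_features = in_features
        self.out_features = out_features
        self.W = Param(_fan_in_uniform(rng, (out_features, in_features), in_features), "W")
        self.b = Param(_fan_in_uniform(rng, (out_features,), in_features), "b")

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, grad):
        x2 = self._x.reshape(-1, self.in_features)
        g2 = grad.reshape(-1, self.out_features)
        self.W.grad += g2.T @ x2
        self.b.grad += g2.sum(axis=0)
        return grad @ self.W.value

    def params(self):
        return [self.W, self.b]


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Conv1d(Layer):
    """1-D convolution (cross-correlation), stride 1, no padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        fan_in = in_channels * kernel_size
        self.W = Param(_fan_in_uniform(rng, (out_channels, in_channels, kernel_size), fan_in), "W")
        self.b = Param(_fan_in_uniform(rng, (out_channels,), fan_in), "b")

    def forward(self, x, training=False, rng=None):
        if x.shape[2] < self.k:
            raise ValueError(f"input length {x.shape[2]} shorter than kernel {self.k}")
        B, C, L = x.shape
        Lout = L - self.k + 1
        cols = sliding_window_view(x, self.k, axis=2)          # (B, C, Lout, k)
        self._cols = cols.transpose(0, 2, 1, 3).reshape(B, Lout, C * self.k)
        self._in_shape = x.shape
        W2 = self.W.value.reshape(self.out_channels, -1)
        out = self._cols @ W2.T + self.b.value                 # (B, Lout, O)
        return out.transpose(0, 2, 1)

    def backward(self, grad):
        B, C, L = self._in_shape
        Lout = L - self.k + 1
        g2 = grad.transpose(0, 2, 1)                           # (B, Lout, O)
        self.W.grad += np.einsum("blo,blf->of", g2, self._cols).reshape(self.W.value.shape)
        self.b.grad += g2.sum(axis=(0, 1))
        W2 = self.W.value.reshape(self.out_channels, -1)
        dcols = (g2 @ W2).reshape(B, Lout, C, self.k)
        dx = np.zeros(self._in_shape)
        for m in range(self.k):                                # k is small (3)
            dx[:, :, m:m + Lout] += dcols[:, :, :, m].transpose(0, 2, 1)
        return dx

    def params(self):
        return [self.W, self.b]


class BatchNorm1d(Layer):
    """Channel-wise batch normalisation for (batch, channels, length) tensors.

    Training normalises with batch statistics over the batch and time axes and
    updates exponential running averages (momentum 0.1); inference applies the
    running averages, making it a deterministic affine map.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels), "gamma")
        self.beta = Param(np.zeros(channels), "beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, training=False, rng=None):
        if training:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            m = x.shape[0] * x.shape[2]
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            unbiased = var * m / max(m - 1, 1)
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
        else:
            mu, var = self.running_mean, self.running_var
        self._invstd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu[None, :, None]) * self._invstd[None, :, None]
        self._training = training
        return self.gamma.value[None, :, None] * self._xhat + self.beta.value[None, :, None]

    def backward(self, grad):
        self.gamma.grad += (grad * self._xhat).sum(axis=(0, 2))
        self.beta.grad += grad.sum(axis=(0, 2))
        dxhat = grad * self.gamma.value[None, :, None]
        if not self._training:
            return dxhat * self._invstd[None, :, None]
        m = grad.shape[0] * grad.shape[2]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * self._xhat).sum(axis=(0, 2), keepdims=True)
        return (self._invstd[None, :, None] / m) * (m * dxhat - s1 - self._xhat * s2)

    def params(self):
        return [self.gamma, self.beta]


class MaxPool1d(Layer):
    """Non-overlapping max pooling; an odd trailing sample is dropped (floor)."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, training=False, rng=None):
        B, C, L = x.shape
        Lout = L // self.size
        xv = x[:, :, :Lout * self.size].reshape(B, C, Lout, self.size)
        self._argmax = xv.argmax(axis=3)
        self._in_shape = x.shape
        return xv.max(axis=3)

    def backward(self, grad):
        B, C, L = self._in_shape
        Lout = L // self.size
        dx = np.zeros((B, C, Lout, self.size))
        np.put_along_axis(dx, self._argmax[..., None], grad[..., None], axis=3)
        out = np.zeros(self._in_shape)
        out[:, :, :Lout * self.size] = dx.reshape(B, C, Lout * self.size)
        return out


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Reshape(Layer):
    """Reshape trailing axes, keeping the batch axis."""

    def __init__(self, shape: tuple[int, ...]):
        self.shape = shape

    def forward(self, x, training=False, rng=None):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Frame(Layer):
    """Cut a (batch, channels, length) window into non-overlapping frames:
    output (batch, length // frame_len, channels * frame_len).

    Used to present raw multi-channel signals to recurrent layers as a short
    sequence of sample blocks instead of one step per sample."""

    def __init__(self, frame_len: int):
        if frame_len < 1:
            raise ValueError("frame_len must be >= 1")
        self.frame_len = frame_len

    def forward(self, x, training=False, rng=None):
        B, C, L = x.shape
        self._in_shape = x.shape
        T = L // self.frame_len
        out = x[:, :, :T * self.frame_len].reshape(B, C, T, self.frame_len)
        return out.transpose(0, 2, 1, 3).reshape(B, T, C * self.frame_len)

    def backward(self, grad):
        B, C, L = self._in_shape
        T = L // self.frame_len
        g = grad.reshape(B, T, C, self.frame_len).transpose(0, 2, 1, 3)
        out = np.zeros(self._in_shape)
        out[:, :, :T * self.frame_len] = g.reshape(B, C, T * self.frame_len)
        return out


class Transpose(Layer):
    """Swap axes 1 and 2, e.g. (batch, channels, time) -> (batch, time, channels)."""

    def forward(self, x, training=False, rng=None):
        return x.transpose(0, 2, 1)

    def backward(self, grad):
        return grad.transpose(0, 2, 1)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float = 0.5):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def forward(self, x, training=False, rng=None):
        if not training or self.p == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in training mode needs an rng")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, training=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]
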