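"""Transformer encoder: sinusoidal positional encoding, scaled dot-product
multi-head self-attention, and post-norm residual blocks.

The encoder follows the classical design: input + positional encoding, then
per layer MHA -> add & layer-norm -> position-wise feed-forward -> add &
layer-norm. Layer normalisation standardises each sequence position across the
embedding axis before a learned affine.
"""
from __future__ import annotations

import numpy as np

from .layers import Layer, Linear, Param

__all__ = ["positional_encoding", "scaled_attention", "LayerNorm",
           "MultiHeadAttention", "TransformerEncoderLayer", "TransformerEncoder"]


def positional_encoding(seq_len: int, d_model: int) -> np.ndarray:
    """Sinusoidal encoding: PE[pos, 2i] = sin(pos / 10000^(2i/d)),
    PE[pos, 2i+1] = cos(pos / 10000^(2i/d))."""
    if d_model % 2:
        raise ValueError("d_model must be even for sinusoidal positional encoding")
    pos = np.arange(seq_len)[:, None]
    i = np.arange(d_model // 2)[None, :]
    angle = pos / np.power(10000.0, 2.0 * i / d_model)
    pe = np.empty((seq_len, d_model))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def _softmax_last(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def scaled_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray) -> np.ndarray:
    """softmax(Q K^T / sqrt(D_K)) V for single (seq, d) matrices."""
    Q, K, V = (np.asarray(m, dtype=float) for m in (Q, K, V))
    if Q.shape[-1] != K.shape[-1] or K.shape[-2] != V.shape[-2]:
        raise ValueError("incompatible attention shapes")
    dk = Q.shape[-1]
    if dk <= 0:
        raise ValueError("inner dimension must be positive")
    weights = _softmax_last(Q @ np.swapaxes(K, -1, -2) / np.sqrt(dk))
    return weights @ V


class LayerNorm(Layer):
    """Per-position normalisation over the last axis with learned affine."""

    def __init__(self, d_model: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Param(np.ones(d_model), "gamma")
        self.beta = Param(np.zeros(d_model), "beta")

    def forward(self, x, training=False, rng=None):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._invstd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._invstd
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, grad):
        d = grad.shape[-1]
        axes = tuple(range(grad.ndim - 1))
        self.gamma.grad += (grad * self._xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        dxhat = grad * self.gamma.value
        s1 = dxhat.sum(axis=-1, keepdims=True)
        s2 = (dxhat * self._xhat).sum(axis=-1, keepdims=True)
        return (self._invstd / d) * (d * dxhat - s1 - self._xhat * s2)

    def params(self):
        return [self.gamma, self.beta]


class MultiHeadAttention(Layer):
    """Self-attention with h parallel heads and an output projection."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.d_model = d_model
        self.n_heads = n_heads
        self.dk = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def _split(self, x):
        B, T, _ = x.shape
        return x.reshape(B, T, self.n_heads, self.dk).transpose(0, 2, 1, 3)

    def _merge(self, x):
        B, h, T, dk = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, T, h * dk)

    def forward(self, x, training=False, rng=None):
        Q = self._split(self.wq.forward(x))
        K = self._split(self.wk.forward(x))
        V = self._split(self.wv.forward(x))
        scores = Q @ K.transpose(0, 1, 3, 2) / np.sqrt(self.dk)
        A = _softmax_last(scores)
        ctx = A @ V
        self._Q, self._K, self._V, self._A = Q, K, V, A
        return self.wo.forward(self._merge(ctx))

    def backward(self, grad):
        dctx = self._split(self.wo.backward(grad))
        A, Q, K, V = self._A, self._Q, self._K, self._V
        dA = dctx @ V.transpose(0, 1, 3, 2)
        dV = A.transpose(0, 1, 3, 2) @ dctx
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dS /= np.sqrt(self.dk)
        dQ = dS @ K
        dK = dS.transpose(0, 1, 3, 2) @ Q
        dx = self.wq.backward(self._merge(dQ))
        dx = dx + self.wk.backward(self._merge(dK))
        dx = dx + self.wv.backward(self._merge(dV))
        return dx

    def params(self):
        return [*self.wq.params(), *self.wk.params(), *self.wv.params(),
                *self.wo.params()]


class TransformerEncoderLayer(Layer):
    def __init__(self, d_model: int, n_heads: int, ff_dim: int,
                 rng: np.random.Generator, eps: float = 1e-5):
        self.mha = MultiHeadAttention(d_model, n_heads, rng)
        self.norm1 = LayerNorm(d_model, eps)
        self.ff1 = Linear(d_model, ff_dim, rng)
        self.ff2 = Linear(ff_dim, d_model, rng)
        self.norm2 = LayerNorm(d_model, eps)

    def forward(self, x, training=False, rng=None):
        a = self.mha.forward(x, training, rng)
        x1 = self.norm1.forward(x + a)
        h = self.ff1.forward(x1)
        self._relu_mask = h > 0
        f = self.ff2.forward(h * self._relu_mask)
        return self.norm2.forward(x1 + f)

    def backward(self, grad):
        g = self.norm2.backward(grad)
        gf = self.ff2.backward(g) * self._relu_mask
        gx1 = g + self.ff1.backward(gf)
        g = self.norm1.backward(gx1)
        return g + self.mha.backward(g)

    def params(self):
        return [*self.mha.params(), *self.norm1.params(), *self.ff1.params(),
                *self.ff2.params(), *self.norm2.params()]


class TransformerEncoder(Layer):
    """Positional encoding followed by a stack of encoder layers.

    Operates on (batch, seq_len, d_model); the positional table is built
    lazily for the observed sequence length.
    """

    def __init__(self, d_model: int, n_heads: int, n_layers: int, ff_dim: int,
                 rng: np.random.Generator, eps: float = 1e-5):
        self.d_model = d_model
        self.blocks = [TransformerEncoderLayer(d_model, n_heads, ff_dim, rng, eps)
                       for _ in range(n_layers)]
        self._pe: np.ndarray | None = None

    def forward(self, x, training=False, rng=None):
        T = x.shape[1]
        if self._pe is None or self._pe.shape[0] != T:
            self._pe = positional_encoding(T, self.d_model)
        x = x + self._pe[None]
        for blk in self.blocks:
            x = blk.forward(x, training, rng)
        return x

    def backward(self, grad):
        for blk in reversed(self.blocks):
            grad = blk.backward(grad)
        return grad                                    # d(x + PE)/dx = identity

    def params(self):
        return [p for blk in self.blocks for p in blk.params()]
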