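"""Multi-layer LSTM with full backpropagation through time.

Gate equations (sigmoid forget/input/output gates, tanh candidate):

    F_t = sigmoid(X_t Wxf + H_{t-1} Whf + b_f)
    I_t = sigmoid(X_t Wxi + H_{t-1} Whi + b_i)
    C~_t = tanh(X_t Wxc + H_{t-1} Whc + b_c)
    C_t = F_t * C_{t-1} + I_t * C~_t
    O_t = sigmoid(X_t Wxo + H_{t-1} Who + b_o)
    H_t = O_t * tanh(C_t)

Input is batch-first (batch, time, features); the classification head consumes
the last layer's final hidden state. Gate weights are packed [I, F, C~, O]
along the output axis of (4H x D) matrices.
"""
from __future__ import annotations

import numpy as np

from .layers import Layer, Param, _fan_in_uniform

__all__ = ["LSTM"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTM(Layer):
    """Stacked LSTM returning the final hidden state of the top layer."""

    def __init__(self, input_size: int, hidden_size: int, num_layers: int,
                 rng: np.random.Generator):
        self.input_size = input_size
        self.hidden_size = hidden_size
        self.num_layers = num_layers
        self.Wx: list[Param] = []
        self.Wh: list[Param] = []
        self.b: list[Param] = []
        H = hidden_size
        for layer in range(num_layers):
            D = input_size if layer == 0 else H
            self.Wx.append(Param(_fan_in_uniform(rng, (4 * H, D), H), f"Wx{layer}"))
            self.Wh.append(Param(_fan_in_uniform(rng, (4 * H, H), H), f"Wh{layer}"))
            b = Param(_fan_in_uniform(rng, (4 * H,), H), f"b{layer}")
            b.value[H:2 * H] = 1.0    # open forget gates at init (standard trick)
            self.b.append(b)

    def forward(self, x, training=False, rng=None):
        B, T, _ = x.shape
        H = self.hidden_size
        self._caches = []
        seq = x
        for layer in range(self.num_layers):
            Wx, Wh, b = self.Wx[layer].value, self.Wh[layer].value, self.b[layer].value
            # precompute input projections for all steps at once
            xa = seq @ Wx.T + b                       # (B, T, 4H)
            h = np.zeros((B, H))
            c = np.zeros((B, H))
            hs = np.empty((B, T, H))
            cache = {"x": seq, "i": np.empty((B, T, H)), "f": np.empty((B, T, H)),
                     "g": np.empty((B, T, H)), "o": np.empty((B, T, H)),
                     "c": np.empty((B, T, H)), "c_prev": np.empty((B, T, H)),
                     "h_prev": np.empty((B, T, H))}
            for t in range(T):
                a = xa[:, t] + h @ Wh.T
                i = _sigmoid(a[:, :H])
                f = _sigmoid(a[:, H:2 * H])
                g = np.tanh(a[:, 2 * H:3 * H])
                o = _sigmoid(a[:, 3 * H:])
                cache["c_prev"][:, t] = c
                cache["h_prev"][:, t] = h
                c = f * c + i * g
                h = o * np.tanh(c)
                cache["i"][:, t], cache["f"][:, t] = i, f
                cache["g"][:, t], cache["o"][:, t] = g, o
                cache["c"][:, t] = c
                hs[:, t] = h
            self._caches.append(cache)
            seq = hs
        self._T = T
        return seq[:, -1]                              # (B, H)

    def backward(self, grad):
        B = grad.shape[0]
        H = self.hidden_size
        T = self._T
        # gradient w.r.t. the top layer's full output sequence
        dh_seq = np.zeros((B, T, H))
        dh_seq[:, -1] = grad
        for layer in reversed(range(self.num_layers)):
            cache = self._caches[layer]
            Wx, Wh = self.Wx[layer].value, self.Wh[layer].value
            D = cache["x"].shape[2]
            dx_seq = np.zeros((B, T, D))
            dh_next = np.zeros((B, H))
            dc_next = np.zeros((B, H))
            dWx = np.zeros_like(Wx)
            dWh = np.zeros_like(Wh)
            db = np.zeros(4 * H)
            for t in reversed(range(T)):
                i, f = cache["i"][:, t], cache["f"][:, t]
                g, o = cache["g"][:, t], cache["o"][:, t]
                c, c_prev = cache["c"][:, t], cache["c_prev"][:, t]
                tanh_c = np.tanh(c)
                dh = dh_seq[:, t] + dh_next
                do = dh * tanh_c
                dc = dh * o * (1 - tanh_c ** 2) + dc_next
                di = dc * g
                df = dc * c_prev
                dg = dc * i
                dc_next = dc * f
                da = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                     dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
                dWx += da.T @ cache["x"][:, t]
                dWh += da.T @ cache["h_prev"][:, t]
                db += da.sum(axis=0)
                dx_seq[:, t] = da @ Wx
                dh_next = da @ Wh
            self.Wx[layer].grad += dWx
            self.Wh[layer].grad += dWh
            self.b[layer].grad += db
            dh_seq = dx_seq                            # feeds the layer below
        return dh_seq                                  # (B, T, input_size)

    def params(self):
        return [*self.Wx, *self.Wh, *self.b]
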