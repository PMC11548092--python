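"""Softmax and multi-class cross-entropy with its analytic gradient."""
from __future__ import annotations

import numpy as np

__all__ = ["softmax", "softmax_cross_entropy"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits.

    L = -(1/n) sum_i log softmax(logits_i)[y_i]; grad = (softmax - onehot)/n.
    """
    n, k = logits.shape
    p = softmax(logits)
    eps = 1e-300
    loss = float(-np.mean(np.log(p[np.arange(n), y] + eps)))
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n
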