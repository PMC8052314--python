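"""Losses on raw logits, each returning (scalar loss, gradient wrt logits).

Working on logits keeps the sigmoid/softmax numerics stable: the BCE
gradient collapses to ``sigmoid(z) - t`` and the softmax cross-entropy
gradient to ``p - onehot(y)``, with no log-of-small-number hazards.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sigmoid", "bce_with_logits", "softmax_cross_entropy", "l1_on_sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float32)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy of sigmoid(z) against soft targets t."""
    # softplus(z) - z*t, computed stably as max(z,0) - z*t + log1p(exp(-|z|))
    loss = np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))
    grad = (sigmoid(z) - t) / z.size
    return float(loss.mean()), grad.astype(np.float32)


def softmax_cross_entropy(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy for integer class targets y over logits (N, K)."""
    zs = z - z.max(axis=1, keepdims=True)
    logp = zs - np.log(np.exp(zs).sum(axis=1, keepdims=True))
    n = z.shape[0]
    loss = -logp[np.arange(n), y].mean()
    grad = np.exp(logp)
    grad[np.arange(n), y] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


def l1_on_sigmoid(z: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error of sigmoid(z) against targets t in [0, 1]."""
    p = sigmoid(z)
    diff = p - t
    loss = float(np.abs(diff).mean())
    grad = np.sign(diff) * p * (1.0 - p) / z.size
    return loss, grad.astype(np.float32)
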