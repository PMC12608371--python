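"""Numerically stable activations and losses.

The binary cross-entropy is evaluated in its fused sigmoid + log-sum-exp
form, ``max(x, 0) - x*y + log(1 + exp(-|x|))``, which is finite for any
finite logits; the naive ``-y log σ(x) - (1-y) log(1-σ(x))`` overflows
once ``σ`` saturates.  Softmax and cross-entropy subtract the row maximum
before exponentiating.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Logistic function 1 / (1 + e^-x), stable for large |x|."""
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(
    logits: np.ndarray, targets: np.ndarray, return_grad: bool = False
):
    """Mean binary cross-entropy of logits against {0,1} targets.

    Returns the scalar loss, or ``(loss, grad)`` with
    ``grad = (σ(x) - y) / N`` when ``return_grad`` is set.
    """
    x = np.asarray(logits, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty batch")
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: logits {x.shape} vs targets {y.shape}")
    if not np.isin(np.unique(y), (0.0, 1.0)).all():
        raise ValueError("targets must be strictly binary {0,1}")
    per_elem = np.maximum(x, 0.0) - x * y + np.log1p(np.exp(-np.abs(x)))
    loss = float(per_elem.mean())
    if not return_grad:
        return loss
    grad = ((sigmoid(x) - y) / x.size).astype(np.float32)
    return loss, grad


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """exp(x_i) / Σ_j exp(x_j) with max-subtraction for stability."""
    x = np.asarray(logits, dtype=np.float64)
    x = x - x.max(axis=axis, keepdims=True)
    ex = np.exp(x)
    return ex / ex.sum(axis=axis, keepdims=True)


def log_softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    x = np.asarray(logits, dtype=np.float64)
    x = x - x.max(axis=axis, keepdims=True)
    return x - np.log(np.exp(x).sum(axis=axis, keepdims=True))


def cross_entropy(
    logits: np.ndarray, labels: np.ndarray, return_grad: bool = False
):
    """Mean categorical cross-entropy of (B, K) logits against int labels."""
    x = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if x.ndim != 2:
        raise ValueError("logits must be (batch, classes)")
    b, k = x.shape
    if labels.shape != (b,):
        raise ValueError("labels must be a (batch,) integer vector")
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError("label index out of range")
    logp = log_softmax(x, axis=1)
    loss = float(-logp[np.arange(b), labels].mean())
    if not return_grad:
        return loss
    grad = np.exp(logp)
    grad[np.arange(b), labels] -= 1.0
    return loss, (grad / b).astype(np.float32)
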