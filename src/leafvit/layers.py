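"""Low-level numpy building blocks with paired forward/backward functions.

Every forward returns ``(output, cache)`` and the matching backward consumes
``(grad_output, cache)``; parameters live in plain dicts of float64 arrays so
a whole model's gradient check can be driven by finite differences.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

LN_EPS = 1e-5

# Python-float constants stay "weak" scalars and never upcast float32 arrays
_SQRT2 = float(np.sqrt(2.0))
_INV_SQRT_2PI = float(1.0 / np.sqrt(2.0 * np.pi))


def gelu(x: np.ndarray) -> np.ndarray:
    """Exact (erf-based) GELU: x * Phi(x)."""
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    """d/dx [x * Phi(x)] = Phi(x) + x * phi(x)."""
    phi = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
    return 0.5 * (1.0 + erf(x / _SQRT2)) + x * phi


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def layer_norm(x, gamma, beta):
    """Row-wise LayerNorm over the last axis with learnable scale/shift."""
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + LN_EPS)
    xhat = (x - mu) * inv
    out = gamma * xhat + beta
    return out, (xhat, inv, gamma)


def layer_norm_backward(dout, cache):
    xhat, inv, gamma = cache
    dgamma = np.sum(dout * xhat, axis=tuple(range(dout.ndim - 1)))
    dbeta = np.sum(dout, axis=tuple(range(dout.ndim - 1)))
    dxhat = dout * gamma
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dgamma, dbeta


def linear(x, W, b=None):
    out = x @ W
    if b is not None:
        out = out + b
    return out, (x, W, b is not None)


def linear_backward(dout, cache):
    x, W, has_bias = cache
    dx = dout @ W.T
    # collapse any leading batch axes
    dW = x.reshape(-1, x.shape[-1]).T @ dout.reshape(-1, dout.shape[-1])
    db = dout.reshape(-1, dout.shape[-1]).sum(axis=0) if has_bias else None
    return dx, dW, db


def drop_path_mask(batch: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Stochastic-depth keep mask, one scalar per sample, rescaled by 1/(1-p).

    A dropped sample's entire residual branch is zeroed; kept samples are
    scaled so the branch expectation is unchanged.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("drop_path rate must lie in [0, 1]")
    if rate == 0.0:
        return np.ones((batch, 1, 1))
    if rate == 1.0:
        return np.zeros((batch, 1, 1))
    keep = (rng.random(batch) >= rate).astype(float) / (1.0 - rate)
    return keep[:, None, None]


def dropout_mask(shape, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Inverted-dropout mask: zeros with probability ``rate``, else 1/(1-p)."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("dropout rate must lie in [0, 1)")
    if rate == 0.0:
        return np.ones(shape)
    return (rng.random(shape) >= rate).astype(float) / (1.0 - rate)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch; returns (loss, probs, dlogits)."""
    probs = softmax(logits, axis=-1)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return loss, probs, dlogits
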