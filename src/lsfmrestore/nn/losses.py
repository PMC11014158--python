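"""Losses returning (scalar loss, gradient w.r.t. prediction)."""

from __future__ import annotations

import numpy as np

_EPS = 1e-7


def mse(pred: np.ndarray, target: np.ndarray):
    diff = pred - target
    loss = float(np.mean(diff.astype(np.float64) ** 2))
    grad = (2.0 / diff.size) * diff
    return loss, grad.astype(pred.dtype)


def bce(pred: np.ndarray, target: np.ndarray):
    """Binary cross entropy on [0,1] targets; predictions are clipped away
    from {0,1} for numerical safety."""
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    t = target
    loss = float(-np.mean(t * np.log(p.astype(np.float64)) + (1 - t) * np.log1p(-p.astype(np.float64))))
    grad = (p - t) / (p * (1.0 - p)) / p.size
    return loss, grad.astype(pred.dtype)
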