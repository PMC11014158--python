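"""Minimal NumPy neural-network layers.

Layout convention is channels-last: images are ``(N, H, W, C)`` and z-slice
sequences are ``(N, T, H, W, C)``. Convolutions are evaluated as a sum of
shifted-slab matmuls (one BLAS gemm per kernel tap), which keeps CPU
training of the restoration networks practical without materialising im2col
matrices. Every layer implements ``forward(x, training)`` and
``backward(dy)``; gradients are accumulated into ``grads`` keyed like
``params``. Correctness of each backward pass is pinned by numeric
gradient-check tests.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "ConvTranspose2D",
    "Conv3D",
    "MaxPool2D",
    "Upsample2D",
    "BatchNorm2D",
    "SpatialDropout2D",
    "ReLU",
    "Sigmoid",
    "conv2d_forward",
    "conv2d_backward",
]


def _pad2d(x, pad):
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))


# the single-gemm im2col path is used whenever the column matrix stays
# below this byte budget; beyond it the tap loop avoids materialising
# multi-hundred-MB intermediates
_COLS_BYTES_LIMIT = 24_000_000


def _use_cols(n_pix, c, k, itemsize):
    return n_pix * c * k * k * itemsize <= _COLS_BYTES_LIMIT


def _gather_cols(xp, n, ho, wo, c, k, stride):
    """im2col: (N*Ho*Wo, k*k*C) column matrix, tap order (i, j, c)."""
    si, sj = stride * (ho - 1) + 1, stride * (wo - 1) + 1
    cols = np.empty((n, ho, wo, k * k, c), dtype=xp.dtype)
    t = 0
    for i in range(k):
        for j in range(k):
            cols[:, :, :, t, :] = xp[:, i : i + si : stride, j : j + sj : stride, :]
            t += 1
    return cols.reshape(n * ho * wo, k * k * c)


def conv2d_forward(x, W, b=None, stride=1):
    """'Same'-padded 2-D convolution; ``W`` has shape (k, k, in_ch, out_ch).

    Small-fan-in layers go through an im2col matrix and one gemm; wide
    layers are evaluated tap by tap (y += x_shifted(i, j) @ W[i, j]) to
    avoid materialising huge column matrices."""
    k = W.shape[0]
    pad = k // 2
    n, h, w, c = x.shape
    xp = _pad2d(x, pad)
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    si, sj = stride * (ho - 1) + 1, stride * (wo - 1) + 1
    f = W.shape[3]
    if _use_cols(n * ho * wo, c, k, x.itemsize):
        cols = _gather_cols(xp, n, ho, wo, c, k, stride)
        y = cols @ W.reshape(k * k * c, f)
    else:
        y = np.zeros((n * ho * wo, f), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                slab = np.ascontiguousarray(xp[:, i : i + si : stride, j : j + sj : stride, :])
                y += slab.reshape(n * ho * wo, c) @ W[i, j]
    if b is not None:
        y += b
    return y.reshape(n, ho, wo, f)


def conv2d_backward(dy, x, W, stride=1):
    """Gradients of :func:`conv2d_forward`; returns (dx, dW, db)."""
    k = W.shape[0]
    pad = k // 2
    n, h, w, c = x.shape
    ho, wo = dy.shape[1], dy.shape[2]
    f = W.shape[3]
    si, sj = stride * (ho - 1) + 1, stride * (wo - 1) + 1
    if stride == 1 and not _use_cols(n * h * w, c, k, x.itemsize) and _use_cols(n * h * w, f, k, x.itemsize):
        # narrow output side: work off im2col of dy instead of x.
        # dx is the full correlation of dy with the flipped kernel;
        # dW[i,j] pairs x with dy shifted by the mirrored tap (k-1-i, k-1-j).
        w_flip = W[::-1, ::-1].transpose(0, 1, 3, 2)  # (k, k, f, c)
        dx = conv2d_forward(dy, np.ascontiguousarray(w_flip))
        dyp = _pad2d(dy, pad)
        cols_dy = _gather_cols(dyp, n, ho, wo, f, k, 1)  # (n*h*w, k*k*f)
        g = x.reshape(n * h * w, c).T @ cols_dy  # (c, k*k*f)
        dW = g.reshape(c, k, k, f)[:, ::-1, ::-1].transpose(1, 2, 0, 3)
        db = dy.sum(axis=(0, 1, 2))
        return dx, np.ascontiguousarray(dW), db
    xp = _pad2d(x, pad)
    dyr = dy.reshape(n * ho * wo, f)
    dxp = np.zeros_like(xp)
    if _use_cols(n * ho * wo, c, k, x.itemsize):
        cols = _gather_cols(xp, n, ho, wo, c, k, stride)
        dWf = cols.T @ dyr  # (k*k*c, f)
        dW = dWf.reshape(k, k, c, f)
        dcols = (dyr @ W.reshape(k * k * c, f).T).reshape(n, ho, wo, k * k, c)
        t = 0
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + si : stride, j : j + sj : stride, :] += dcols[:, :, :, t, :]
                t += 1
    else:
        dW = np.empty_like(W)
        for i in range(k):
            for j in range(k):
                slab = np.ascontiguousarray(xp[:, i : i + si : stride, j : j + sj : stride, :])
                dW[i, j] = slab.reshape(n * ho * wo, c).T @ dyr
                dxp[:, i : i + si : stride, j : j + sj : stride, :] += (dyr @ W[i, j].T).reshape(
                    n, ho, wo, c
                )
    db = dyr.sum(axis=0)
    dx = dxp[:, pad : pad + h, pad : pad + w, :] if pad else dxp
    return dx, dW, db


class Layer:
    """Base class; stateless layers only override forward/backward."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self):
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


class Conv2D(Layer):
    """2-D convolution, 'same' padding, He-initialised."""

    def __init__(self, in_ch, out_ch, k, rng, stride=1, dtype=np.float32, weight_scale=None):
        super().__init__()
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        fan_in = in_ch * k * k
        scale = weight_scale if weight_scale is not None else np.sqrt(2.0 / fan_in)
        self.params = {
            "W": (rng.standard_normal((k, k, in_ch, out_ch)) * scale).astype(dtype),
            "b": np.zeros(out_ch, dtype=dtype),
        }
        self.zero_grad()

    def forward(self, x, training=False):
        self._x = x
        return conv2d_forward(x, self.params["W"], self.params["b"], self.stride)

    def backward(self, dy):
        dx, dW, db = conv2d_backward(dy, self._x, self.params["W"], self.stride)
        self.grads["W"] += dW
        self.grads["b"] += db
        return dx


class ConvTranspose2D(Layer):
    """Transposed 2-D convolution (fractional-stride upsampling).

    Implemented as the adjoint of a strided 'same' convolution: with
    ``stride=2`` an (H, W) input maps to (2H, 2W); with ``stride=1`` the
    spatial size is preserved. Weight shape is (k, k, out_ch, in_ch), the
    kernel of the underlying out-space -> in-space convolution.
    """

    def __init__(self, in_ch, out_ch, k, rng, stride=1, dtype=np.float32, weight_scale=None):
        super().__init__()
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        fan_in = in_ch * k * k
        scale = weight_scale if weight_scale is not None else np.sqrt(2.0 / fan_in)
        self.params = {
            "W": (rng.standard_normal((k, k, out_ch, in_ch)) * scale).astype(dtype),
            "b": np.zeros(out_ch, dtype=dtype),
        }
        self.zero_grad()

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        k, stride, pad = self.k, self.stride, self.k // 2
        W = self.params["W"]
        h2, w2 = h * stride, w * stride
        si, sj = stride * (h - 1) + 1, stride * (w - 1) + 1
        self._x = x
        xr = x.reshape(n * h * w, c)
        yp = np.zeros((n, h2 + 2 * pad, w2 + 2 * pad, self.out_ch), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                yp[:, i : i + si : stride, j : j + sj : stride, :] += (xr @ W[i, j].T).reshape(
                    n, h, w, self.out_ch
                )
        y = yp[:, pad : pad + h2, pad : pad + w2, :] if pad else yp
        return y + self.params["b"]

    def backward(self, dy):
        n, h, w, c = self._x.shape
        k, stride, pad = self.k, self.stride, self.k // 2
        W = self.params["W"]
        si, sj = stride * (h - 1) + 1, stride * (w - 1) + 1
        dyp = _pad2d(dy, pad)
        xr = self._x.reshape(n * h * w, c)
        if _use_cols(n * h * w, self.out_ch, k, dy.itemsize):
            cols = _gather_cols(dyp, n, h, w, self.out_ch, k, stride)
            self.grads["W"] += (cols.T @ xr).reshape(k, k, self.out_ch, c)
            dx = cols @ W.reshape(k * k * self.out_ch, c)
        else:
            dx = np.zeros((n * h * w, c), dtype=dy.dtype)
            for i in range(k):
                for j in range(k):
                    slab = np.ascontiguousarray(dyp[:, i : i + si : stride, j : j + sj : stride, :])
                    slab = slab.reshape(n * h * w, self.out_ch)
                    self.grads["W"][i, j] += slab.T @ xr
                    dx += slab @ W[i, j]
        self.grads["b"] += dy.sum(axis=(0, 1, 2))
        return dx.reshape(self._x.shape)


class Conv3D(Layer):
    """3-D convolution over (T, H, W), 'same' padding, channels-last."""

    def __init__(self, in_ch, out_ch, k, rng, dtype=np.float32, weight_scale=None):
        super().__init__()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        fan_in = in_ch * k**3
        scale = weight_scale if weight_scale is not None else np.sqrt(2.0 / fan_in)
        self.params = {
            "W": (rng.standard_normal((k, k, k, in_ch, out_ch)) * scale).astype(dtype),
            "b": np.zeros(out_ch, dtype=dtype),
        }
        self.zero_grad()

    def forward(self, x, training=False):
        n, t, h, w, c = x.shape
        k, p = self.k, self.k // 2
        self._x = x
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
        W = self.params["W"]
        y = np.zeros((n * t * h * w, self.out_ch), dtype=x.dtype)
        for a in range(k):
            for i in range(k):
                for j in range(k):
                    slab = np.ascontiguousarray(xp[:, a : a + t, i : i + h, j : j + w, :])
                    y += slab.reshape(n * t * h * w, c) @ W[a, i, j]
        y += self.params["b"]
        return y.reshape(n, t, h, w, self.out_ch)

    def backward(self, dy):
        n, t, h, w, c = self._x.shape
        k, p = self.k, self.k // 2
        W = self.params["W"]
        xp = np.pad(self._x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
        dyr = dy.reshape(n * t * h * w, self.out_ch)
        dxp = np.zeros_like(xp)
        for a in range(k):
            for i in range(k):
                for j in range(k):
                    slab = np.ascontiguousarray(xp[:, a : a + t, i : i + h, j : j + w, :])
                    self.grads["W"][a, i, j] += slab.reshape(n * t * h * w, c).T @ dyr
                    dxp[:, a : a + t, i : i + h, j : j + w, :] += (dyr @ W[a, i, j].T).reshape(
                        n, t, h, w, c
                    )
        self.grads["b"] += dyr.sum(axis=0)
        return dxp[:, p : p + t, p : p + h, p : p + w, :]


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2. Requires even spatial extents."""

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        y = xr.max(axis=(2, 4))
        mask = (xr == y[:, :, None, :, None, :]).astype(x.dtype)
        count = mask.sum(axis=(2, 4), keepdims=True)
        self._mask = mask / count  # ties share the gradient
        self._shape = x.shape
        return y

    def backward(self, dy):
        n, h, w, c = self._shape
        d = self._mask * dy[:, :, None, :, None, :]
        return d.reshape(n, h, w, c)


class Upsample2D(Layer):
    """2x nearest-neighbour upsampling."""

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy):
        n, h, w, c = self._shape
        return dy.reshape(n, h, 2, w, 2, c).sum(axis=(2, 4))


class BatchNorm2D(Layer):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, ch, momentum=0.9, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(ch, dtype=dtype), "beta": np.zeros(ch, dtype=dtype)}
        self.buffers = {
            "running_mean": np.zeros(ch, dtype=dtype),
            "running_var": np.ones(ch, dtype=dtype),
        }
        self.zero_grad()

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        ch = x.shape[-1]
        if training:
            flat = x.reshape(-1, ch)
            m = float(flat.shape[0])
            mean = np.einsum("nc->c", flat) / m
            var = np.einsum("nc,nc->c", flat, flat) / m - mean * mean
            mom = self.momentum
            self.buffers["running_mean"] = (mom * self.buffers["running_mean"] + (1 - mom) * mean).astype(x.dtype)
            self.buffers["running_var"] = (mom * self.buffers["running_var"] + (1 - mom) * var).astype(x.dtype)
        else:
            mean, var = self.buffers["running_mean"], self.buffers["running_var"]
        ivar = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        self._training, self._x, self._mean, self._ivar = training, x, mean.astype(x.dtype), ivar
        # fused affine: y = x * (gamma*ivar) + (beta - mean*gamma*ivar)
        scale = self.params["gamma"] * ivar
        return x * scale + (self.params["beta"] - mean * scale)

    def backward(self, dy):
        axes = tuple(range(dy.ndim - 1))
        ivar = self._ivar
        xhat = (self._x - self._mean) * ivar
        self.grads["gamma"] += (dy * xhat).sum(axis=axes)
        self.grads["beta"] += dy.sum(axis=axes)
        if not self._training:
            return dy * self.params["gamma"] * ivar
        m = float(np.prod([dy.shape[a] for a in axes]))
        gamma = self.params["gamma"]
        s1 = dy.sum(axis=axes) * gamma
        ch = dy.shape[-1]
        s2 = np.einsum(
            "nc,nc->c",
            np.ascontiguousarray(dy).reshape(-1, ch),
            np.ascontiguousarray(xhat).reshape(-1, ch),
        ) * gamma
        dx = dy * (gamma * m)
        dx -= s1
        dx -= xhat * s2
        dx *= ivar / m
        return dx


class SpatialDropout2D(Layer):
    """Drops whole feature maps; identity at inference."""

    def __init__(self, rate, rng):
        super().__init__()
        self.rate, self.rng = rate, rng

    def forward(self, x, training=False):
        if not training or self.rate <= 0:
            self._mask = None
            return x
        keep = (self.rng.random((x.shape[0], 1, 1, x.shape[-1])) >= self.rate)
        self._mask = keep.astype(x.dtype) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x, training=False):
        from scipy.special import expit  # numerically stable logistic

        self._y = expit(x)
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)
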