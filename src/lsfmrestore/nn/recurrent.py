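"""Convolutional LSTM layer with full backpropagation through time.

Processes z-slice sequences shaped (N, T, H, W, C) and always returns the
full hidden-state sequence (N, T, H, W, hid), which is what the volumetric
distortion auto-encoder requires. Gate order in the fused weight tensors is
(i, f, g, o); the forget-gate bias starts at 1 so early training does not
wash out state.
"""

from __future__ import annotations

import numpy as np

from .layers import Layer, conv2d_backward, conv2d_forward


from scipy.special import expit as _sigmoid  # numerically stable logistic


class ConvLSTM2D(Layer):
    def __init__(self, in_ch, hid, k, rng, dtype=np.float32):
        super().__init__()
        self.in_ch, self.hid, self.k = in_ch, hid, k
        sx = np.sqrt(1.0 / (in_ch * k * k))
        sh = np.sqrt(1.0 / (hid * k * k))
        b = np.zeros(4 * hid, dtype=dtype)
        b[hid : 2 * hid] = 1.0  # forget gate
        self.params = {
            "Wx": (rng.standard_normal((k, k, in_ch, 4 * hid)) * sx).astype(dtype),
            "Wh": (rng.standard_normal((k, k, hid, 4 * hid)) * sh).astype(dtype),
            "b": b,
        }
        self.zero_grad()

    def forward(self, x, training=False):
        n, t, h, w, c = x.shape
        hid = self.hid
        self._x = x
        # input-to-gate convolutions for all timesteps at once
        zx = conv2d_forward(x.reshape(n * t, h, w, c), self.params["Wx"]).reshape(
            n, t, h, w, 4 * hid
        )
        hs = np.zeros((n, t, h, w, hid), dtype=x.dtype)
        gates = np.empty((n, t, h, w, 4 * hid), dtype=x.dtype)  # activated i,f,g,o
        tanh_c = np.empty((n, t, h, w, hid), dtype=x.dtype)
        cs = np.empty((n, t, h, w, hid), dtype=x.dtype)
        h_prev = np.zeros((n, h, w, hid), dtype=x.dtype)
        c_prev = np.zeros((n, h, w, hid), dtype=x.dtype)
        for ti in range(t):
            z = zx[:, ti] + conv2d_forward(h_prev, self.params["Wh"]) + self.params["b"]
            i = _sigmoid(z[..., :hid])
            f = _sigmoid(z[..., hid : 2 * hid])
            g = np.tanh(z[..., 2 * hid : 3 * hid])
            o = _sigmoid(z[..., 3 * hid :])
            c_cur = f * c_prev + i * g
            tc = np.tanh(c_cur)
            h_prev = o * tc
            gates[:, ti, ..., :hid] = i
            gates[:, ti, ..., hid : 2 * hid] = f
            gates[:, ti, ..., 2 * hid : 3 * hid] = g
            gates[:, ti, ..., 3 * hid :] = o
            tanh_c[:, ti] = tc
            cs[:, ti] = c_cur
            hs[:, ti] = h_prev
            c_prev = c_cur
        self._gates, self._tanh_c, self._cs, self._hs = gates, tanh_c, cs, hs
        return hs

    def backward(self, dy):
        n, t, h, w, c = self._x.shape
        hid = self.hid
        gates, tanh_c, cs, hs = self._gates, self._tanh_c, self._cs, self._hs
        gWx = np.zeros_like(self.params["Wx"], dtype=np.float64)
        gWh = np.zeros_like(self.params["Wh"], dtype=np.float64)
        gb = np.zeros(4 * hid, dtype=np.float64)
        dx = np.empty_like(self._x)
        dh_next = np.zeros((n, h, w, hid), dtype=dy.dtype)
        dc_next = np.zeros((n, h, w, hid), dtype=dy.dtype)
        zeros = np.zeros((n, h, w, hid), dtype=dy.dtype)
        for ti in range(t - 1, -1, -1):
            i = gates[:, ti, ..., :hid]
            f = gates[:, ti, ..., hid : 2 * hid]
            g = gates[:, ti, ..., 2 * hid : 3 * hid]
            o = gates[:, ti, ..., 3 * hid :]
            tc = tanh_c[:, ti]
            c_prev = cs[:, ti - 1] if ti > 0 else zeros
            h_prev = hs[:, ti - 1] if ti > 0 else zeros
            dh = dy[:, ti] + dh_next
            dc = dc_next + dh * o * (1.0 - tc * tc)
            dz = np.empty((n, h, w, 4 * hid), dtype=dy.dtype)
            dz[..., :hid] = dc * g * i * (1.0 - i)
            dz[..., hid : 2 * hid] = dc * c_prev * f * (1.0 - f)
            dz[..., 2 * hid : 3 * hid] = dc * i * (1.0 - g * g)
            dz[..., 3 * hid :] = dh * tc * o * (1.0 - o)
            dc_next = dc * f
            dxt, dWx_t, db_t = conv2d_backward(dz, self._x[:, ti], self.params["Wx"])
            dh_next, dWh_t, _ = conv2d_backward(dz, h_prev, self.params["Wh"])
            dx[:, ti] = dxt
            gWx += dWx_t
            gWh += dWh_t
            gb += db_t
        self.grads["Wx"] += gWx.astype(self.params["Wx"].dtype)
        self.grads["Wh"] += gWh.astype(self.params["Wh"].dtype)
        self.grads["b"] += gb.astype(self.params["b"].dtype)
        return dx
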