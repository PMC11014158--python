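"""Stochastic optimisers operating in place on layer parameter dicts."""

from __future__ import annotations

import numpy as np


class Optimizer:
    def __init__(self, layers, lr):
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.t = 0

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def step(self):  # pragma: no cover
        raise NotImplementedError


class Adam(Optimizer):
    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(layers, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                p -= self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)


class RMSprop(Optimizer):
    def __init__(self, layers, lr=1e-3, rho=0.9, eps=1e-7):
        super().__init__(layers, lr)
        self.rho, self.eps = rho, eps
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self):
        self.t += 1
        for layer, v in zip(self.layers, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                v[k] = self.rho * v[k] + (1 - self.rho) * g * g
                p -= self.lr * g / (np.sqrt(v[k]) + self.eps)
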