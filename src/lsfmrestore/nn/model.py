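"""Model container, serialization and the shared training loop.

A trained network is stored as a single ``.npz`` holding the weight arrays,
the batch-norm running statistics, a JSON training manifest, and a
fingerprint — a SHA-256 hash of the canonical architecture config. Loading
weights onto a model built from a different config is rejected by comparing
fingerprints, so a model file can never silently drive the wrong
architecture.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json

import numpy as np


class ModelError(ValueError):
    """Fingerprint mismatch or malformed model file."""


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch):
        super().__init__(f"loss became non-finite at epoch {epoch}")
        self.epoch = epoch


def config_fingerprint(config) -> str:
    if dataclasses.is_dataclass(config):
        config = dataclasses.asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


class Model:
    """Base class: subclasses set ``self.layers`` and implement forward/backward."""

    layers: list

    def forward(self, x, training=False):  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover
        raise NotImplementedError

    def predict(self, x, batch_size=8):
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(self.forward(x[i : i + batch_size], training=False))
        return np.concatenate(out, axis=0)

    def state_arrays(self):
        state = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                state[f"layer{i}.{k}"] = v
            for k, v in layer.buffers.items():
                state[f"layer{i}.buf.{k}"] = v
        return state

    def load_state_arrays(self, state):
        for i, layer in enumerate(self.layers):
            for k in layer.params:
                layer.params[k][...] = state[f"layer{i}.{k}"]
            for k in layer.buffers:
                layer.buffers[k][...] = state[f"layer{i}.buf.{k}"]


def save_model(path, model: Model, fingerprint: str, manifest: dict):
    arrays = model.state_arrays()
    arrays["__fingerprint__"] = np.array(fingerprint)
    arrays["__manifest__"] = np.array(json.dumps(manifest))
    np.savez(path, **arrays)


def load_model(path, model: Model, fingerprint: str) -> dict:
    """Load weights into ``model``; returns the manifest. Raises
    :class:`ModelError` if the stored fingerprint does not match."""
    with np.load(path, allow_pickle=False) as data:
        stored = str(data["__fingerprint__"])
        if stored != fingerprint:
            raise ModelError(
                f"model fingerprint {stored[:12]}… does not match config {fingerprint[:12]}…"
            )
        manifest = json.loads(str(data["__manifest__"]))
        model.load_state_arrays({k: data[k] for k in data.files if not k.startswith("__")})
    return manifest


def fit(
    model: Model,
    inputs: np.ndarray,
    targets: np.ndarray,
    loss_fn,
    optimizer,
    epochs: int,
    batch_size: int,
    rng: np.random.Generator,
    shuffle: bool = True,
    verbose: bool = False,
):
    """Mini-batch training; returns the per-epoch mean loss curve."""
    n = inputs.shape[0]
    if n == 0:
        raise ValueError("empty training corpus")
    curve = []
    for epoch in range(epochs):
        order = rng.permutation(n) if shuffle else np.arange(n)
        total = 0.0
        seen = 0
        for i in range(0, n, batch_size):
            idx = order[i : i + batch_size]
            xb, yb = inputs[idx], targets[idx]
            pred = model.forward(xb, training=True)
            loss, grad = loss_fn(pred, yb)
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            optimizer.zero_grad()
            model.backward(grad)
            optimizer.step()
            total += loss * len(idx)
            seen += len(idx)
        curve.append(total / seen)
        if verbose:
            print(f"epoch {epoch + 1}/{epochs}  loss {curve[-1]:.6g}")
    return curve
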