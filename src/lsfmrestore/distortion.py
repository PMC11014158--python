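"""Axial-distortion correction networks.

Two auto-encoders learn the inverse of the axial elongation transform from
bead calibration pairs (distorted stack -> rendered isotropic target):

* a two-layer 2-D convolutional auto-encoder on 128x128 slice patches —
  one convolution (default 1024 filters, 3x3) encoding, one transposed
  convolution decoding to a sigmoid output; trained with RMSprop on binary
  cross entropy;
* a ConvLSTM auto-encoder on 31-slice sequences of 32x32 patches —
  CLSTM(16) -> CLSTM(32) -> CLSTM(32) -> CLSTM(16) -> Conv3D(1, 3x3x3) with
  sigmoid, every recurrent layer emitting full sequences; trained with Adam
  (lr 1e-4, batch 8) on MSE. Unlike the per-slice model, it sees axial
  context and can distinguish an elongated blob from an in-focus one.

Training on presence-filtered blocks only (regions that actually contain
beads) avoids the mean-collapse failure mode where the network averages a
mostly-black corpus into flat gray output; the output/target variance ratio
is recorded in the manifest as a contrast-loss monitor.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .beads import DistortionCorpus
from .dae import TrainedModel, init_output_bias
from .errors import DataError, ParameterError, RangeError, SizeError
from .imgio import ImageStack, patchify, stitch


@dataclass
class ConvAEConfig:
    filters: int = 1024
    kernel: int = 3
    lr: float = 1e-3
    epochs: int = 100
    batch_size: int = 8
    seed: int = 0
    patch: int = 128

    def __post_init__(self):
        if self.filters < 1:
            raise ParameterError("filters must be positive")

    @classmethod
    def ci_profile(cls, **overrides):
        # scaled-down profile: fewer filters, and a higher learning rate so
        # the BCE loss converges within the reduced epoch budget
        defaults = dict(filters=64, epochs=20, lr=3e-3)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class ConvLSTMConfig:
    enc_filters: tuple[int, int] = (16, 32)
    dec_filters: tuple[int, int] = (32, 16)
    kernel: int = 3
    final_kernel: int = 3
    seq_len: int = 31
    patch: int = 32
    lr: float = 1e-4
    batch_size: int = 8
    epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.seq_len < 3 or self.patch < 8:
            raise ParameterError("need seq_len >= 3 and patch >= 8")

    @classmethod
    def ci_profile(cls, **overrides):
        defaults = dict(epochs=10, lr=1e-3)
        defaults.update(overrides)
        return cls(**defaults)


class ConvAENet(nn.Model):
    """conv(filters, kxk, stride 1, ReLU) -> tconv(1, kxk) -> sigmoid."""

    def __init__(self, config: ConvAEConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        f, k = config.filters, config.kernel
        self.layers = [
            nn.Conv2D(1, f, k, rng),
            nn.ReLU(),
            nn.ConvTranspose2D(f, 1, k, rng, stride=1, weight_scale=np.sqrt(1.0 / (f * k * k))),
            nn.Sigmoid(),
        ]

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameter_count(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params.values())


class ConvLSTMAENet(nn.Model):
    """Four ConvLSTM layers (full sequences) + Conv3D head with sigmoid."""

    def __init__(self, config: ConvLSTMConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        e1, e2 = config.enc_filters
        d1, d2 = config.dec_filters
        k = config.kernel
        self.layers = [
            nn.ConvLSTM2D(1, e1, k, rng),
            nn.ConvLSTM2D(e1, e2, k, rng),
            nn.ConvLSTM2D(e2, d1, k, rng),
            nn.ConvLSTM2D(d1, d2, k, rng),
            nn.Conv3D(d2, 1, config.final_kernel, rng, weight_scale=np.sqrt(1.0 / (d2 * config.final_kernel**3))),
            nn.Sigmoid(),
        ]

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def shape_walk(self):
        c = self.config
        x = np.zeros((1, c.seq_len, c.patch, c.patch, 1), dtype=np.float32)
        shapes = []
        for layer in self.layers:
            x = layer.forward(x, False)
            shapes.append(x.shape)
        return shapes


def build_conv_ae(config: ConvAEConfig) -> ConvAENet:
    return ConvAENet(config)


def build_convlstm_ae(config: ConvLSTMConfig) -> ConvLSTMAENet:
    return ConvLSTMAENet(config)


def _variance_ratio(model, inputs_nhwc, targets_nhwc, batch_size):
    pred = model.predict(inputs_nhwc, batch_size=batch_size)
    tv = float(np.var(targets_nhwc))
    return float(np.var(pred)) / tv if tv > 0 else float("nan")


def train_conv_ae(model: ConvAENet, corpus: DistortionCorpus, config: ConvAEConfig | None = None, verbose=False) -> TrainedModel:
    """Binary-cross-entropy training with RMSprop on aligned patch pairs."""
    config = config or model.config
    if corpus.mode != "patch128":
        raise DataError(f"conv AE needs a patch128 corpus, got '{corpus.mode}'")
    if corpus.targets.min() < 0 or corpus.targets.max() > 1:
        raise RangeError("BCE targets must lie in [0, 1]")
    x = corpus.inputs[..., None].astype(np.float32)
    y = corpus.targets[..., None].astype(np.float32)
    init_output_bias(model.layers[2], y)  # start the sigmoid at the target mean
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.RMSprop(model.layers, lr=config.lr)
    t0 = time.time()
    curve = nn.fit(model, x, y, nn.bce, opt, config.epochs, config.batch_size, rng, verbose=verbose)
    manifest = {
        "kind": "conv_ae",
        "config": asdict(config),
        "corpus": corpus.manifest,
        "loss_curve": curve,
        "output_target_variance_ratio": _variance_ratio(model, x, y, config.batch_size),
        "train_seconds": time.time() - t0,
    }
    return TrainedModel(model, config, manifest)


def train_convlstm_ae(model: ConvLSTMAENet, corpus: DistortionCorpus, config: ConvLSTMConfig | None = None, verbose=False) -> TrainedModel:
    """MSE training with Adam on aligned 31x32x32 sequence pairs."""
    config = config or model.config
    if corpus.mode != "seq31x32":
        raise DataError(f"ConvLSTM AE needs a seq31x32 corpus, got '{corpus.mode}'")
    if corpus.n_blocks == 0:
        raise DataError("empty corpus")
    x = corpus.inputs[..., None].astype(np.float32)
    y = corpus.targets[..., None].astype(np.float32)
    init_output_bias(model.layers[4], y)  # start the sigmoid at the target mean
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(model.layers, lr=config.lr)
    t0 = time.time()
    curve = nn.fit(model, x, y, nn.mse, opt, config.epochs, config.batch_size, rng, verbose=verbose)
    manifest = {
        "kind": "convlstm_ae",
        "config": asdict(config),
        "corpus": corpus.manifest,
        "loss_curve": curve,
        "output_target_variance_ratio": _variance_ratio(model, x, y, config.batch_size),
        "train_seconds": time.time() - t0,
    }
    return TrainedModel(model, config, manifest)


def load_trained_conv_ae(path, config: ConvAEConfig) -> TrainedModel:
    net = ConvAENet(config)
    manifest = nn.load_model(path, net, nn.config_fingerprint(config))
    return TrainedModel(net, config, manifest)


def load_trained_convlstm_ae(path, config: ConvLSTMConfig) -> TrainedModel:
    net = ConvLSTMAENet(config)
    manifest = nn.load_model(path, net, nn.config_fingerprint(config))
    return TrainedModel(net, config, manifest)


def _correct_patch_mode(stack: ImageStack, model: TrainedModel) -> np.ndarray:
    patch = model.config.patch
    out = np.empty_like(stack.data)
    for z in range(stack.n_slices):
        patches, grid = patchify(stack.data[z], patch)
        pred = model.net.predict(patches[..., None].astype(np.float32), batch_size=model.config.batch_size)[..., 0]
        out[z] = stitch(pred, grid)
    return out


def _correct_sequence_mode(stack: ImageStack, model: TrainedModel) -> np.ndarray:
    cfg = model.config
    seq, patch = cfg.seq_len, cfg.patch
    z_extent = stack.n_slices
    if z_extent < seq:
        raise SizeError(f"stack depth {z_extent} < sequence length {seq}")
    starts = list(range(0, z_extent - seq + 1, seq))
    if starts[-1] + seq < z_extent:
        starts.append(z_extent - seq)  # trailing window; later window wins
    out = np.empty_like(stack.data)
    for z0 in starts:
        window = stack.data[z0 : z0 + seq]
        _, grid = patchify(window[0], patch)
        tiles = np.stack([patchify(s, patch)[0] for s in window], axis=1)  # (np, seq, ph, pw)
        pred = model.net.predict(tiles[..., None].astype(np.float32), batch_size=cfg.batch_size)[..., 0]
        for z_off in range(seq):
            out[z0 + z_off] = stitch(pred[:, z_off], grid)
    return out


def correct_stack(stack: ImageStack, model: TrainedModel) -> ImageStack:
    """Apply a trained distortion model to a full stack; output shape always
    equals input shape. Patch models run per slice; sequence models run on
    non-overlapping z-windows with a final overlapping window covering any
    trailing slices (the later window's values win in the overlap)."""
    if isinstance(model.config, ConvAEConfig):
        out = _correct_patch_mode(stack, model)
    elif isinstance(model.config, ConvLSTMConfig):
        out = _correct_sequence_mode(stack, model)
    else:
        raise ParameterError(f"unsupported model config {type(model.config).__name__}")
    return ImageStack(np.clip(out, 0, 1), stack.bit_depth, stack.voxel_size)
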