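"""Numeric gradient checks and contracts for the NumPy network engine.

Each layer's analytic backward pass is compared against central finite
differences in float64 on tiny tensors; a failure here would silently break
every trained network downstream.
"""

import numpy as np
import pytest

from lsfmrestore import nn

RNG = np.random.default_rng(42)


def _num_grad(f, x, eps=1e-5):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


def _check_layer(layer, x, training=True, tol=1e-6):
    """Check input and parameter gradients of a scalar loss sum(w * y)."""
    w = np.asarray(RNG.standard_normal(layer.forward(x, training).shape))

    def loss():
        return float(np.sum(w * layer.forward(x, training)))

    layer.forward(x, training)
    layer.zero_grad()
    dx = layer.backward(w.copy())
    assert np.allclose(dx, _num_grad(loss, x), atol=tol), "input gradient mismatch"
    for name in layer.params:
        analytic = layer.grads[name]
        numeric = _num_grad(loss, layer.params[name])
        assert np.allclose(analytic, numeric, atol=tol), f"grad mismatch for {name}"


def _f64(layer):
    for k in layer.params:
        layer.params[k] = layer.params[k].astype(np.float64)
    for k in layer.buffers:
        layer.buffers[k] = layer.buffers[k].astype(np.float64)
    layer.zero_grad()
    return layer


@pytest.mark.parametrize("stride", [1, 2])
def test_conv2d_gradients(stride):
    layer = _f64(nn.Conv2D(2, 3, 3, RNG, stride=stride))
    x = RNG.standard_normal((2, 6, 6, 2))
    _check_layer(layer, x)


def test_conv2d_5x5_gradients():
    layer = _f64(nn.Conv2D(1, 2, 5, RNG))
    _check_layer(layer, RNG.standard_normal((1, 8, 8, 1)))


@pytest.mark.parametrize("stride", [1, 2])
def test_conv_transpose2d_gradients_and_shape(stride):
    layer = _f64(nn.ConvTranspose2D(3, 2, 3, RNG, stride=stride))
    x = RNG.standard_normal((2, 5, 4, 3))
    y = layer.forward(x)
    assert y.shape == (2, 5 * stride, 4 * stride, 2)
    _check_layer(layer, x)


def test_conv3d_gradients():
    layer = _f64(nn.Conv3D(2, 1, 3, RNG))
    _check_layer(layer, RNG.standard_normal((1, 4, 4, 4, 2)))


def test_maxpool_gradients():
    _check_layer(nn.MaxPool2D(), RNG.standard_normal((2, 4, 4, 3)))


def test_upsample_gradients_and_shape():
    layer = nn.Upsample2D()
    x = RNG.standard_normal((2, 3, 4, 2))
    assert layer.forward(x).shape == (2, 6, 8, 2)
    _check_layer(layer, x)


def test_batchnorm_gradients_training_mode():
    layer = _f64(nn.BatchNorm2D(3))
    _check_layer(layer, RNG.standard_normal((4, 3, 3, 3)), tol=1e-5)


def test_batchnorm_inference_uses_running_stats():
    layer = nn.BatchNorm2D(2)
    x = np.asarray(RNG.standard_normal((8, 4, 4, 2)), dtype=np.float32)
    layer.forward(x, training=True)
    y1 = layer.forward(x[:2], training=False)
    y2 = layer.forward(x[:2], training=False)
    np.testing.assert_array_equal(y1, y2)


def test_relu_sigmoid_gradients():
    _check_layer(nn.ReLU(), RNG.standard_normal((2, 3, 3, 2)))
    _check_layer(nn.Sigmoid(), RNG.standard_normal((2, 3, 3, 2)))


def test_spatial_dropout_scales_and_is_identity_at_eval():
    layer = nn.SpatialDropout2D(0.5, np.random.default_rng(0))
    x = np.ones((4, 2, 2, 8))
    y = layer.forward(x, training=True)
    assert set(np.unique(y)) <= {0.0, 2.0}  # inverted scaling keeps expectation
    np.testing.assert_array_equal(layer.forward(x, training=False), x)


def test_convlstm_gradients():
    layer = _f64(nn.ConvLSTM2D(2, 3, 3, RNG))
    x = RNG.standard_normal((2, 3, 4, 4, 2))
    y = layer.forward(x, training=True)
    assert y.shape == (2, 3, 4, 4, 3)  # full sequence returned
    _check_layer(layer, x, tol=1e-5)


def test_losses_gradients():
    pred = RNG.uniform(0.1, 0.9, (3, 4))
    target = RNG.uniform(0, 1, (3, 4))
    for fn in (nn.mse, nn.bce):
        _, grad = fn(pred, target)
        num = _num_grad(lambda: fn(pred, target)[0], pred)
        assert np.allclose(grad, num, atol=1e-6)


def test_adam_and_rmsprop_reduce_quadratic():
    for opt_cls in (nn.Adam, nn.RMSprop):
        layer = nn.Conv2D(1, 1, 3, np.random.default_rng(1))
        opt = opt_cls([layer], lr=1e-2)
        x = np.asarray(RNG.standard_normal((4, 6, 6, 1)), dtype=np.float32)
        target = np.zeros((4, 6, 6, 1), dtype=np.float32)
        losses = []
        for _ in range(30):
            pred = layer.forward(x, training=True)
            loss, grad = nn.mse(pred, target)
            opt.zero_grad()
            layer.backward(grad)
            opt.step()
            losses.append(loss)
        assert losses[-1] < 0.2 * losses[0]


def test_model_save_load_fingerprint(tmp_path):
    class Tiny(nn.Model):
        def __init__(self, seed):
            self.layers = [nn.Conv2D(1, 2, 3, np.random.default_rng(seed))]

        def forward(self, x, training=False):
            return self.layers[0].forward(x, training)

    m = Tiny(0)
    fp = nn.config_fingerprint({"arch": "tiny", "filters": 2})
    nn.save_model(tmp_path / "m.npz", m, fp, {"note": "test"})
    m2 = Tiny(99)
    manifest = nn.load_model(tmp_path / "m.npz", m2, fp)
    assert manifest["note"] == "test"
    np.testing.assert_array_equal(m.layers[0].params["W"], m2.layers[0].params["W"])
    with pytest.raises(nn.ModelError):
        nn.load_model(tmp_path / "m.npz", m2, nn.config_fingerprint({"arch": "other"}))
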