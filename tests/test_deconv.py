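"""Richardson-Lucy deconvolution against brute-force oracles."""

import numpy as np
import pytest
import scipy.ndimage as ndi

from lsfmrestore import errors
from lsfmrestore.deconv import (
    PSFModel,
    RLConfig,
    convolve_observe,
    gaussian_psf,
    naive_fourier_deconvolve,
    rl_deconvolve,
    rl_step,
)
from lsfmrestore.metrics import psnr
from lsfmrestore.noise import NoiseParams, synth_clean_image

RNG = np.random.default_rng(11)


def reflect_conv_oracle(img, kernel):
    """Nested-loop 'same' convolution with reflective boundaries."""
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    # scipy.ndimage "reflect" duplicates the edge sample, i.e. numpy "symmetric"
    padded = np.pad(img, ((ph, ph), (pw, pw)), mode="symmetric")
    out = np.zeros_like(img, dtype=np.float64)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            acc = 0.0
            for a in range(kh):
                for b in range(kw):
                    # true convolution: kernel indices flipped
                    acc += kernel[kh - 1 - a, kw - 1 - b] * padded[i + a, j + b]
            out[i, j] = acc
    return out


def rl_update_oracle(current, observed, kernel, eps=1e-12):
    """Textbook RL update via the loop-convolution oracle."""
    denom = reflect_conv_oracle(current, kernel) + eps
    return current * reflect_conv_oracle(observed / denom, kernel[::-1, ::-1])


class TestGaussianPSF:
    def test_normalised_and_centred(self):
        psf = gaussian_psf(2.0, 1.0, 11)
        assert abs(psf.kernel.sum() - 1.0) < 1e-12
        assert psf.kernel[5, 5] == psf.kernel.max()

    def test_delta_limit(self):
        psf = gaussian_psf(1e-3, 1e-3, 5)
        assert psf.kernel[2, 2] >= 1 - 1e-6

    def test_matches_direct_formula(self):
        psf = gaussian_psf(2.0, 1.0, 11)
        y, x = np.mgrid[-5:6, -5:6]
        direct = np.exp(-(y**2 / 8.0 + x**2 / 2.0))
        direct /= direct.sum()
        np.testing.assert_allclose(psf.kernel, direct, atol=1e-12)

    def test_even_size_rejected(self):
        with pytest.raises(errors.ParameterError):
            gaussian_psf(1, 1, 10)

    def test_negative_kernel_rejected(self):
        with pytest.raises(errors.RangeError):
            PSFModel(np.array([[1.0, -0.1, 0.1]]).T @ np.array([[1.0, 1, 1]]))


class TestRLStep:
    def test_gamma_one_returns_box_smoothed_input_exactly(self):
        cur = RNG.random((16, 16))
        out = rl_step(cur, cur, gaussian_psf(1, 1, 5), RLConfig(gamma=1.0))
        np.testing.assert_array_equal(out, ndi.uniform_filter(cur, 3, mode="reflect"))

    def test_delta_psf_fixed_point(self):
        obs = RNG.random((12, 12)) + 0.1
        psf = PSFModel(np.array([[0.0, 0, 0], [0, 1, 0], [0, 0, 0]]))
        out = rl_step(obs, obs, psf, RLConfig(gamma=0.0))
        np.testing.assert_allclose(out, obs, atol=1e-9)

    @pytest.mark.parametrize(
        "shape,kernel",
        [
            ((1, 5), np.array([[0.25, 0.5, 0.25]])),
            ((7, 7), None),  # random 3x3 kernel below
        ],
    )
    def test_matches_loop_oracle(self, shape, kernel):
        rng = np.random.default_rng(5)
        observed = rng.random(shape) + 0.05
        current = observed.copy()
        if kernel is None:
            kernel = rng.random((3, 3))
        kernel = kernel / kernel.sum()
        psf = PSFModel(kernel)
        ours = rl_step(current, observed, psf, RLConfig(gamma=0.0))
        oracle = rl_update_oracle(current, observed, psf.kernel)
        np.testing.assert_allclose(ours, oracle, atol=1e-10)

    def test_toy_spike_row(self):
        observed = np.array([[0.0, 0, 10, 0, 0]])
        psf = PSFModel(np.array([[0.25, 0.5, 0.25]]))
        ours = rl_step(observed, observed, psf, RLConfig(gamma=0.0))
        oracle = rl_update_oracle(observed, observed, psf.kernel)
        np.testing.assert_allclose(ours, oracle, atol=1e-10)

    def test_shape_mismatch(self):
        with pytest.raises(errors.ShapeError):
            rl_step(np.zeros((4, 4)), np.zeros((5, 5)), gaussian_psf(1, 1, 3), RLConfig())


class TestRLDeconvolve:
    def test_zero_iterations_is_identity(self):
        obs = RNG.random((8, 8))
        np.testing.assert_array_equal(rl_deconvolve(obs, gaussian_psf(1, 1, 5), RLConfig(n_iters=0)), obs)

    def test_restoration_improves_psnr(self):
        clean = synth_clean_image((128, 128), seed=7)
        psf = gaussian_psf(2, 2, 21)
        blurred = convolve_observe(clean, psf)
        restored = rl_deconvolve(blurred, psf, RLConfig(n_iters=30, gamma=0.0))
        assert psnr(clean, np.clip(restored, 0, 1)) > psnr(clean, blurred) + 3.0

    def test_flux_conserved_at_gamma_zero(self):
        clean = synth_clean_image((64, 64), n_cells=2, cell_radius_range=(3, 6), seed=3)
        psf = gaussian_psf(2, 2, 11)
        blurred = convolve_observe(clean, psf)
        _, flux = rl_deconvolve(blurred, psf, RLConfig(n_iters=25, gamma=0.0), return_flux=True)
        log = np.asarray(flux[0])
        assert np.abs(log - log[0]).max() / log[0] < 0.01

    def test_negative_input_rejected(self):
        with pytest.raises(errors.RangeError):
            rl_deconvolve(np.array([[-0.1, 0.2]]), gaussian_psf(1, 1, 3))


class TestForwardModel:
    def test_delta_psf_identity(self):
        clean = RNG.random((16, 16))
        psf = PSFModel(np.eye(1))
        np.testing.assert_allclose(convolve_observe(clean, psf), clean, atol=1e-12)

    def test_constant_image_unchanged_by_normalised_psf(self):
        const = np.full((32, 32), 0.4)
        out = convolve_observe(const, gaussian_psf(3, 3, 11))
        np.testing.assert_allclose(out, 0.4, atol=1e-12)

    def test_noise_hookup(self):
        clean = np.full((32, 32), 0.5)
        out = convolve_observe(clean, gaussian_psf(1, 1, 5), NoiseParams(seed=0))
        assert out.std() > 0


class TestFourierAntiExample:
    def test_direct_inversion_amplifies_noise(self):
        """Spectral division restores a noise-free blur but explodes under
        even mild additive noise — the reason RL is used instead."""
        clean = synth_clean_image((64, 64), n_cells=2, cell_radius_range=(3, 6), seed=1)
        psf = gaussian_psf(2, 2, 21)
        blurred = convolve_observe(clean, psf)
        noisy = np.clip(blurred + np.random.default_rng(0).normal(0, 1e-3, blurred.shape), 0, 1)
        inverted = naive_fourier_deconvolve(noisy, psf)
        rl = rl_deconvolve(noisy, psf, RLConfig(n_iters=20, gamma=0.01))
        assert psnr(clean, np.clip(inverted, 0, 1)) < psnr(clean, np.clip(rl, 0, 1)) - 10
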