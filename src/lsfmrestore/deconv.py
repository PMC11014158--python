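"""Richardson–Lucy deconvolution with flux-preserving regularisation.

The forward model is D = O (*) H + N: the recorded slice D is the true scene
O convolved with the optical transfer kernel H (the PSF) plus noise. The RL
iteration is the multiplicative maximum-likelihood update under Poisson
statistics,

    O_{n+1} = O_n * [ (D / (H (*) O_n)) (*) H_flip ],

and the flux-preserving variant blends each iterate with a box-smoothed copy
O*_n = R (*) O_n weighted by gamma:

    O_{n+1} = (1 - gamma) * O_n * [ (D / (H (*) O_n)) (*) H_flip ] + gamma * O*_n.

gamma = 0 recovers plain RL; gamma = 1 returns the smoothed iterate exactly.
All convolutions use reflective boundaries, which keeps total flux conserved
for a normalised kernel. A direct Fourier inversion of the forward model is
provided only as a documented anti-example: dividing by the transfer
function amplifies noise wherever its spectrum is small.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .errors import ParameterError, RangeError, ShapeError
from .imgio import ImageStack
from .noise import NoiseParams, corrupt


@dataclass
class PSFModel:
    """A centred, normalised 2-D kernel; ``params`` records its provenance."""

    kernel: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        k = np.asarray(self.kernel, dtype=np.float64)
        if k.ndim != 2:
            raise ShapeError("PSF kernel must be 2-D")
        if k.shape[0] % 2 == 0 or k.shape[1] % 2 == 0:
            raise ParameterError("PSF kernel sides must be odd (centred)")
        if (k < 0).any():
            raise RangeError("PSF kernel entries must be non-negative")
        s = k.sum()
        if s <= 0:
            raise RangeError("PSF kernel must have positive mass")
        self.kernel = k / s

    @property
    def flipped(self) -> np.ndarray:
        """The adjoint kernel H_flip (spatial flip of H)."""
        return self.kernel[::-1, ::-1]


@dataclass
class RLConfig:
    n_iters: int = 50
    gamma: float = 0.01  # regularisation weight
    smooth_kernel_size: int = 3  # side of the average filter R
    epsilon: float = 1e-12  # division guard
    init: str = "observed"  # "observed" | "flat"

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ParameterError("gamma must lie in [0, 1]")
        if self.n_iters < 0:
            raise ParameterError("n_iters must be >= 0")
        if self.smooth_kernel_size < 3 or self.smooth_kernel_size % 2 == 0:
            raise ParameterError("smooth_kernel_size must be odd and >= 3")
        if self.init not in ("observed", "flat"):
            raise ParameterError("init must be 'observed' or 'flat'")


def gaussian_psf(sigma_y: float, sigma_x: float, size: int) -> PSFModel:
    """Parametric anisotropic Gaussian PSF on an odd square grid."""
    if sigma_y <= 0 or sigma_x <= 0:
        raise ParameterError("PSF sigmas must be > 0")
    if size % 2 == 0:
        raise ParameterError("PSF size must be odd")
    half = size // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1]
    kernel = np.exp(-(y**2 / (2 * sigma_y**2) + x**2 / (2 * sigma_x**2)))
    return PSFModel(kernel, {"type": "gaussian", "sigma_y": sigma_y, "sigma_x": sigma_x, "size": size})


def load_psf(path) -> PSFModel:
    """Load a measured kernel from a TIFF and normalise it."""
    from .imgio import read_stack

    stack = read_stack(path)
    kernel = stack.data[0] if stack.n_slices == 1 else stack.data.sum(axis=0)
    return PSFModel(kernel, {"type": "measured", "source": str(path)})


def _conv(img, kernel):
    return ndi.convolve(img, kernel, mode="reflect")


def rl_step(current: np.ndarray, observed: np.ndarray, psf: PSFModel, config: RLConfig) -> np.ndarray:
    """One flux-preserving RL update on a single slice."""
    current = np.asarray(current, dtype=np.float64)
    observed = np.asarray(observed, dtype=np.float64)
    if current.shape != observed.shape:
        raise ShapeError(f"shape mismatch: {current.shape} vs {observed.shape}")
    smoothed = ndi.uniform_filter(current, size=config.smooth_kernel_size, mode="reflect")
    if config.gamma == 1.0:
        return smoothed
    denom = _conv(current, psf.kernel) + config.epsilon
    update = current * _conv(observed / denom, psf.flipped)
    return (1.0 - config.gamma) * update + config.gamma * smoothed


def rl_deconvolve(
    observed: ImageStack | np.ndarray,
    psf: PSFModel,
    config: RLConfig | None = None,
    return_flux: bool = False,
):
    """Deconvolve each slice independently for ``config.n_iters`` iterations.

    Returns the restored stack; with ``return_flux=True`` also a per-slice
    list of total-intensity values, one entry per iteration including the
    initial state (the flux log).
    """
    config = config or RLConfig()
    is_stack = isinstance(observed, ImageStack)
    data = observed.data if is_stack else np.asarray(observed, dtype=np.float64)
    if data.ndim == 2:
        data = data[None]
    if (data < 0).any():
        raise RangeError("observed intensities must be non-negative")
    out = np.empty_like(data, dtype=np.float64)
    flux_log: list[list[float]] = []
    for z in range(data.shape[0]):
        obs = np.asarray(data[z], dtype=np.float64)
        cur = obs.copy() if config.init == "observed" else np.full_like(obs, obs.mean())
        log = [float(cur.sum())]
        for _ in range(config.n_iters):
            cur = rl_step(cur, obs, psf, config)
            log.append(float(cur.sum()))
        out[z] = np.maximum(cur, 0.0)
        flux_log.append(log)
    if is_stack:
        result = ImageStack(np.clip(out, 0.0, 1.0), observed.bit_depth, observed.voxel_size)
    else:
        result = out if observed.ndim == 3 else out[0]
    return (result, flux_log) if return_flux else result


def convolve_observe(
    clean: ImageStack | np.ndarray,
    psf: PSFModel,
    noise: NoiseParams | None = None,
):
    """Forward model D = O (*) H (+ noise): blur each slice, optionally
    corrupt with the mixed Poisson–Gaussian model."""
    is_stack = isinstance(clean, ImageStack)
    data = clean.data if is_stack else np.asarray(clean, dtype=np.float64)
    squeeze = data.ndim == 2
    if squeeze:
        data = data[None]
    blurred = np.stack([_conv(np.asarray(s, dtype=np.float64), psf.kernel) for s in data])
    blurred = np.clip(blurred, 0.0, 1.0)
    if is_stack:
        result = ImageStack(blurred, clean.bit_depth, clean.voxel_size)
    else:
        result = blurred[0] if squeeze else blurred
    if noise is not None:
        result = corrupt(result, noise)
    return result


def naive_fourier_deconvolve(observed: np.ndarray, psf: PSFModel, guard: float = 0.0) -> np.ndarray:
    """Direct spectral division O = F^-1[F(D)/F(H)].

    Kept as an anti-example: with any additive noise the division explodes
    where the transfer spectrum is small. Tests demonstrate the noise
    amplification; do not use this for restoration.
    """
    observed = np.asarray(observed, dtype=np.float64)
    h, w = observed.shape
    kernel = np.zeros_like(observed)
    kh, kw = psf.kernel.shape
    kernel[:kh, :kw] = psf.kernel
    kernel = np.roll(kernel, (-(kh // 2), -(kw // 2)), axis=(0, 1))
    tf = np.fft.rfft2(kernel)
    spec = np.fft.rfft2(observed) / (tf + guard)
    return np.fft.irfft2(spec, s=(h, w))
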