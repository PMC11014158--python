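"""Classical denoising baselines and the benchmark harness.

Reproduces the comparison design of the denoiser benchmark: every method is
run on the same held-out noisy patches and scored with PSNR and SSIM against
the clean references; the report lists mean, standard error of the mean, and
standard deviation per method, with the raw noisy input always present as
the floor row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage import restoration

from .errors import DataError, ParameterError, RangeError
from .metrics import psnr, ssim


@dataclass
class BaselineSpec:
    name: str
    params: dict = field(default_factory=dict)


def _median(img, params):
    return ndi.median_filter(img, size=params.get("size", 3), mode="reflect")


def _mean(img, params):
    return ndi.uniform_filter(img, size=params.get("size", 3), mode="reflect")


def _bilateral(img, params):
    return restoration.denoise_bilateral(
        img,
        sigma_color=params.get("sigma_color", 0.1),
        sigma_spatial=params.get("sigma_spatial", 1.5),
    )


def _tv(img, params):
    return restoration.denoise_tv_chambolle(img, weight=params.get("weight", 0.1))


def _wavelet_bayes(img, params):
    return restoration.denoise_wavelet(
        img, method="BayesShrink", mode="soft", rescale_sigma=True
    )


def _wavelet_visu(img, params):
    sigma = params.get("sigma")
    if sigma is None:
        sigma = restoration.estimate_sigma(img)
    return restoration.denoise_wavelet(
        img, method="VisuShrink", mode="soft", sigma=sigma, rescale_sigma=True
    )


_REGISTRY = {
    "median": _median,
    "mean": _mean,
    "bilateral": _bilateral,
    "total_variation": _tv,
    "wavelet_bayes": _wavelet_bayes,
    "wavelet_visushrink": _wavelet_visu,
}


def available_baselines():
    return sorted(_REGISTRY)


def run_baseline(spec: BaselineSpec, noisy: np.ndarray) -> np.ndarray:
    """Denoise one slice with the named classical method; output in [0, 1]."""
    if spec.name not in _REGISTRY:
        raise ParameterError(
            f"unknown baseline '{spec.name}'; available: {available_baselines()}"
        )
    noisy = np.asarray(noisy, dtype=np.float64)
    if noisy.min() < 0 or noisy.max() > 1:
        raise RangeError("baseline input must lie in [0, 1]")
    if np.ptp(noisy) == 0:  # constant images are fixed points of every denoiser
        return noisy.copy()
    out = _REGISTRY[spec.name](noisy, spec.params)
    return np.clip(out, 0.0, 1.0)


def _score_rows(name, denoised_list, clean_list):
    ps = np.array([psnr(c, d) for c, d in zip(clean_list, denoised_list)])
    ss = np.array([ssim(c, d) for c, d in zip(clean_list, denoised_list)])
    n = len(ps)
    return {
        "method": name,
        "psnr_mean": ps.mean(),
        "psnr_sem": ps.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
        "psnr_std": ps.std(ddof=1) if n > 1 else 0.0,
        "ssim_mean": ss.mean(),
        "ssim_sem": ss.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
        "ssim_std": ss.std(ddof=1) if n > 1 else 0.0,
        "n": n,
    }


def benchmark(corpus, specs, dae_model=None) -> pd.DataFrame:
    """Score baselines (and optionally a trained denoising auto-encoder) on
    the corpus' held-out pairs. The noisy input row is always included."""
    clean = list(corpus.clean_test)
    noisy = list(corpus.noisy_test)
    if not clean:
        raise DataError("corpus has no held-out test pairs")
    rows = [_score_rows("noisy", noisy, clean)]
    for spec in specs:
        rows.append(_score_rows(spec.name, [run_baseline(spec, x) for x in noisy], clean))
    if dae_model is not None:
        from .dae import denoise_slices

        rows.append(_score_rows("dae", list(denoise_slices(np.stack(noisy), dae_model)), clean))
    return pd.DataFrame(rows)
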