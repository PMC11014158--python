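"""Mixed Poisson–Gaussian corruption and paired training corpora.

The camera model treats each observed pixel z as the true signal y degraded
by signal-dependent shot noise plus signal-independent read noise:

    z = Poisson(g * y) / g + N(0, sigma^2) + offset,   clipped to [0, 1]

where ``g`` (``poisson_gain``) is the photon count per unit normalised
intensity. Dividing the Poisson draw by ``g`` keeps the clean signal as the
mean on the normalised scale, so Var(z) = y/g + sigma^2 — an affine law in y
that the tests verify empirically.

The module also synthesises fluorescence-like clean images (bright somata
plus dim curvilinear filaments on a dark background) to stand in for
undeposited microscope data when building denoising corpora.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import scipy.ndimage as ndi

from .errors import DataError, ParameterError
from .imgio import ImageStack, patchify


@dataclass
class NoiseParams:
    poisson_gain: float = 100.0  # photons per unit intensity
    gauss_sigma: float = 0.02  # additive std, normalised units
    offset: float = 0.0  # constant background
    seed: int = 0

    def __post_init__(self):
        if self.poisson_gain <= 0:
            raise ParameterError("poisson_gain must be > 0")
        if self.gauss_sigma < 0:
            raise ParameterError("gauss_sigma must be >= 0")


def corrupt(clean, params: NoiseParams, rng: np.random.Generator | None = None):
    """Apply the mixed Poisson–Gaussian model; deterministic under the
    params seed. Accepts an :class:`ImageStack` or a bare array in [0, 1]."""
    is_stack = isinstance(clean, ImageStack)
    y = clean.data if is_stack else np.asarray(clean, dtype=np.float64)
    if not np.isfinite(y).all():
        raise DataError("clean input contains non-finite values")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    g = params.poisson_gain
    z = rng.poisson(g * np.asarray(y, dtype=np.float64)) / g
    if params.gauss_sigma > 0:
        z = z + rng.normal(0.0, params.gauss_sigma, size=z.shape)
    z = np.clip(z + params.offset, 0.0, 1.0).astype(np.float32)
    if is_stack:
        return ImageStack(z, clean.bit_depth, clean.voxel_size)
    return z


def synth_clean_image(
    shape=(256, 256),
    n_cells: int = 12,
    cell_radius_range=(4.0, 12.0),
    filament_density: float = 3.0,
    background: float = 0.02,
    seed: int = 0,
) -> np.ndarray:
    """Render a clean fluorescence-like 2-D image.

    ``n_cells`` Gaussian-profile somata (peak 0.5–0.95) are placed with
    rejection sampling so their profiles stay separable; ``filament_density``
    is the expected number of dim random-walk filaments per 256x256 area.
    Deterministic under ``seed``; values in [0, 1].
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    img = np.full((h, w), float(background), dtype=np.float64)

    yy, xx = np.mgrid[0:h, 0:w]
    rmin, rmax = cell_radius_range
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    for _ in range(n_cells):
        for _attempt in range(2000):
            r = rng.uniform(rmin, rmax)
            cy = rng.uniform(2 * r, h - 2 * r)
            cx = rng.uniform(2 * r, w - 2 * r)
            if all(
                np.hypot(cy - py, cx - px) > 2.5 * (r + pr)
                for (py, px), pr in zip(centers, radii)
            ):
                centers.append((cy, cx))
                radii.append(r)
                break
        else:
            raise ParameterError("cannot place cells without overlap; reduce n_cells")
    cells = np.zeros_like(img)
    for (cy, cx), r in zip(centers, radii):
        peak = rng.uniform(0.5, 0.95)
        sigma = r / 2.0
        cells += peak * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))

    n_filaments = int(round(filament_density * h * w / 256.0**2))
    filaments = np.zeros_like(img)
    for _ in range(n_filaments):
        y, x = rng.uniform(0, h), rng.uniform(0, w)
        angle = rng.uniform(0, 2 * np.pi)
        intensity = rng.uniform(0.08, 0.25)
        for _step in range(rng.integers(40, 120)):
            angle += rng.normal(0, 0.25)
            y += np.sin(angle)
            x += np.cos(angle)
            iy, ix = int(round(y)), int(round(x))
            if 0 <= iy < h and 0 <= ix < w:
                filaments[iy, ix] = max(filaments[iy, ix], intensity)
    filaments = ndi.gaussian_filter(filaments, 0.8)

    img = np.clip(img + cells + filaments, 0.0, 1.0)
    return img.astype(np.float32)


@dataclass
class PairedCorpus:
    """Aligned (noisy, clean) patch pairs with a train/test split."""

    noisy_train: np.ndarray
    clean_train: np.ndarray
    noisy_test: np.ndarray
    clean_test: np.ndarray
    manifest: dict

    @property
    def n_train(self):
        return self.noisy_train.shape[0]

    @property
    def n_test(self):
        return self.noisy_test.shape[0]


# the reference experiment used 1237 source images, 1000 of them for training
DEFAULT_TRAIN_FRAC = 1000.0 / 1237.0


def build_pairs(
    clean_images,
    params: NoiseParams,
    patch_size: int = 128,
    train_frac: float = DEFAULT_TRAIN_FRAC,
) -> PairedCorpus:
    """Corrupt clean images and cut aligned patch pairs.

    The split is at the *image* level (seeded shuffle, ``round(train_frac*N)``
    train images) so no source image leaks across the split; patches are then
    taken from each image via :func:`lsfmrestore.imgio.patchify`.
    """
    clean_images = list(clean_images)
    if not clean_images:
        raise DataError("build_pairs needs at least one clean image")
    rng = np.random.default_rng(params.seed)
    n = len(clean_images)
    order = rng.permutation(n)
    n_train = int(round(train_frac * n))

    def _patches(indices):
        noisy_out, clean_out = [], []
        for idx in indices:
            clean = np.asarray(clean_images[idx], dtype=np.float32)
            noisy = corrupt(clean, params, rng=rng)
            cp, _ = patchify(clean, patch_size)
            npch, _ = patchify(noisy, patch_size)
            clean_out.append(cp)
            noisy_out.append(npch)
        if not noisy_out:
            shape = (0, patch_size, patch_size)
            return np.empty(shape, np.float32), np.empty(shape, np.float32)
        return np.concatenate(noisy_out), np.concatenate(clean_out)

    noisy_train, clean_train = _patches(order[:n_train])
    noisy_test, clean_test = _patches(order[n_train:])
    manifest = {
        "seed": params.seed,
        "noise_params": asdict(params),
        "patch_size": patch_size,
        "train_frac": train_frac,
        "n_images": n,
        "n_train_images": n_train,
        "n_train_pairs": int(noisy_train.shape[0]),
        "n_test_pairs": int(noisy_test.shape[0]),
    }
    return PairedCorpus(noisy_train, clean_train, noisy_test, clean_test, manifest)


def save_corpus(corpus: PairedCorpus, directory) -> None:
    """Write the corpus as paired 16-bit TIFF stacks plus a key=value
    manifest (seed, noise parameters, split sizes)."""
    from pathlib import Path

    from .imgio import write_stack

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for split in ("train", "test"):
        noisy = getattr(corpus, f"noisy_{split}")
        clean = getattr(corpus, f"clean_{split}")
        if noisy.shape[0]:
            write_stack(ImageStack(noisy), directory / f"noisy_{split}.tif")
            write_stack(ImageStack(clean), directory / f"clean_{split}.tif")
    with open(directory / "manifest.txt", "w") as fh:
        for key, value in sorted(_flatten(corpus.manifest).items()):
            fh.write(f"{key}={value}\n")


def load_corpus(directory) -> PairedCorpus:
    from pathlib import Path

    from .imgio import read_stack

    directory = Path(directory)
    manifest = {}
    with open(directory / "manifest.txt") as fh:
        for line in fh:
            key, _, value = line.strip().partition("=")
            manifest[key] = value
    arrays = {}
    for split in ("train", "test"):
        path = directory / f"noisy_{split}.tif"
        if path.exists():
            arrays[f"noisy_{split}"] = read_stack(path).data
            arrays[f"clean_{split}"] = read_stack(directory / f"clean_{split}.tif").data
        else:
            arrays[f"noisy_{split}"] = np.empty((0, 1, 1), np.float32)
            arrays[f"clean_{split}"] = np.empty((0, 1, 1), np.float32)
    return PairedCorpus(
        arrays["noisy_train"], arrays["clean_train"],
        arrays["noisy_test"], arrays["clean_test"], manifest,
    )


def _flatten(d, prefix=""):
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        else:
            out[key] = v
    return out
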