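"""CLAHE contrast enhancement — the pipeline's second stage.

Contrast-Limited Adaptive Histogram Equalisation (Zuiderveld's algorithm)
equalises each contextual tile with a clipped histogram and blends the tile
mappings bilinearly, boosting local contrast without overamplifying noise.
This module owns the stage's contract — pinned parameters, [0, 1]
normalisation, determinism — and delegates the equalisation itself to
scikit-image's implementation of the same algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure

from .errors import ParameterError, RangeError
from .imgio import ImageStack


@dataclass
class ClaheConfig:
    clip_limit: float = 0.01  # normalised clipping threshold
    tile_grid: tuple[int, int] = (8, 8)  # (rows, cols) of contextual regions
    nbins: int = 256

    def __post_init__(self):
        if self.clip_limit <= 0:
            raise ParameterError("clip_limit must be > 0")
        if min(self.tile_grid) < 1:
            raise ParameterError("tile counts must be >= 1")


def clahe_enhance(slice2d: np.ndarray, config: ClaheConfig | None = None) -> np.ndarray:
    """Enhance one slice; input and output both live in [0, 1]."""
    config = config or ClaheConfig()
    img = np.asarray(slice2d, dtype=np.float64)
    if img.ndim != 2:
        raise ParameterError("clahe_enhance expects a 2-D slice")
    if img.min() < 0 or img.max() > 1:
        raise RangeError("input must lie in [0, 1]")
    rows, cols = config.tile_grid
    if rows > img.shape[0] or cols > img.shape[1]:
        raise ParameterError(f"tile grid {config.tile_grid} larger than image {img.shape}")
    if np.ptp(img) < 1e-12:
        return img.copy()  # nothing to redistribute
    kernel = (max(1, img.shape[0] // rows), max(1, img.shape[1] // cols))
    out = exposure.equalize_adapthist(
        img, kernel_size=kernel, clip_limit=config.clip_limit, nbins=config.nbins
    )
    return np.clip(out, 0.0, 1.0)


def enhance_stack(stack: ImageStack, config: ClaheConfig | None = None) -> ImageStack:
    out = np.stack([clahe_enhance(s, config) for s in stack.data])
    return ImageStack(out, stack.bit_depth, stack.voxel_size)
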