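"""TIFF stack I/O, intensity normalisation, patch and sequence decomposition.

Everything downstream works on :class:`ImageStack`: a z-ordered float grid in
[0, 1], axis order ``(z, y, x)``. Integer TIFF data (8- or 16-bit) is scaled
by ``2**depth - 1`` on read and re-quantised on write, so a read/write round
trip is exact. Slices are tiled into non-overlapping patches with
edge-replication padding; stitching is the exact left inverse of extraction.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import DataError, FormatError, GridError, RangeError, ShapeError, SizeError

_DEPTH_DTYPES = {8: np.uint8, 16: np.uint16}


@dataclass
class ImageStack:
    """A z-stack of grayscale slices, float in [0, 1], indexed (z, y, x)."""

    data: np.ndarray
    bit_depth: int = 16
    voxel_size: tuple[float, float, float] | None = None  # (dz, dy, dx) in um

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ShapeError(f"expected 2-D slice or 3-D stack, got ndim={arr.ndim}")
        if not np.isfinite(arr).all():
            raise DataError("stack contains non-finite values")
        if arr.min() < 0.0 or arr.max() > 1.0 + 1e-9:
            raise RangeError("stack values must lie in [0, 1]; clip explicitly first")
        if self.bit_depth not in _DEPTH_DTYPES:
            raise FormatError(f"unsupported bit depth {self.bit_depth}")
        self.data = np.clip(arr.astype(np.float32, copy=False), 0.0, 1.0)

    @property
    def shape(self):
        return self.data.shape

    @property
    def n_slices(self):
        return self.data.shape[0]

    def copy(self):
        return ImageStack(self.data.copy(), self.bit_depth, self.voxel_size)


def _load_pages(path: Path) -> np.ndarray:
    try:
        return tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - any reader failure is a format error
        raise FormatError(f"cannot read {path} as TIFF: {exc}") from exc


def read_stack(path) -> ImageStack:
    """Read a multi-page TIFF, single-page TIFF, or a directory of per-slice
    TIFFs (lexicographic order) into a normalised :class:`ImageStack`."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".tif", ".tiff"}
        )
        if not files:
            raise FormatError(f"no TIFF files in directory {path}")
        slices = [_load_pages(p) for p in files]
        shapes = {s.shape for s in slices}
        if len(shapes) > 1:
            raise ShapeError(f"inconsistent slice shapes in {path}: {sorted(shapes)}")
        raw = np.stack(slices)
    else:
        raw = _load_pages(path)
    if raw.ndim == 2:
        raw = raw[None]
    if raw.ndim != 3:
        raise FormatError(f"expected grayscale pages, got shape {raw.shape}")
    if raw.dtype == np.uint8:
        depth = 8
    elif raw.dtype == np.uint16:
        depth = 16
    else:
        raise FormatError(f"unsupported TIFF dtype {raw.dtype}; need uint8/uint16")
    data = raw.astype(np.float32) / (2**depth - 1)
    return ImageStack(data, bit_depth=depth)


def write_stack(stack: ImageStack, path, bit_depth: int | None = None) -> None:
    """Quantise to the target integer depth (round half away from zero) and
    write a multi-page TIFF."""
    depth = stack.bit_depth if bit_depth is None else bit_depth
    if depth not in _DEPTH_DTYPES:
        raise FormatError(f"unsupported bit depth {depth}")
    arr = np.asarray(stack.data, dtype=np.float64)
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise RangeError("values outside [0, 1]; clip before writing")
    scale = 2**depth - 1
    quantised = np.floor(arr * scale + 0.5).astype(_DEPTH_DTYPES[depth])
    os.makedirs(Path(path).parent, exist_ok=True)
    tifffile.imwrite(path, quantised)


@dataclass
class PatchGrid:
    """Tiling metadata; ``origins`` are (row, col) offsets into the padded slice."""

    patch_size: tuple[int, int]
    grid_shape: tuple[int, int]
    padded_shape: tuple[int, int]
    original_shape: tuple[int, int]
    pad_mode: str = "edge"
    origins: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_patches(self):
        return self.grid_shape[0] * self.grid_shape[1]


def patchify(slice2d: np.ndarray, patch_size) -> tuple[np.ndarray, PatchGrid]:
    """Split a 2-D slice into non-overlapping patches in row-major order.

    The slice is edge-padded up to a multiple of the patch size. Returns an
    array of shape (n_patches, ph, pw) and the grid needed by :func:`stitch`.
    """
    if np.isscalar(patch_size):
        patch_size = (int(patch_size), int(patch_size))
    ph, pw = patch_size
    if ph < 8 or pw < 8:
        raise SizeError(f"patch size {patch_size} too small; minimum 8")
    slice2d = np.asarray(slice2d)
    if slice2d.ndim != 2:
        raise ShapeError("patchify expects a 2-D slice")
    h, w = slice2d.shape
    hp = int(np.ceil(h / ph)) * ph
    wp = int(np.ceil(w / pw)) * pw
    padded = np.pad(slice2d, ((0, hp - h), (0, wp - w)), mode="edge")
    rows, cols = hp // ph, wp // pw
    origins = [(r * ph, c * pw) for r in range(rows) for c in range(cols)]
    patches = (
        padded.reshape(rows, ph, cols, pw).transpose(0, 2, 1, 3).reshape(rows * cols, ph, pw)
    )
    grid = PatchGrid((ph, pw), (rows, cols), (hp, wp), (h, w), origins=origins)
    return patches, grid


def stitch(patches, grid: PatchGrid, original_shape=None) -> np.ndarray:
    """Reassemble patches produced by :func:`patchify`; exact inverse."""
    patches = np.asarray(patches)
    if patches.shape[0] != grid.n_patches:
        raise GridError(
            f"{patches.shape[0]} patches for a {grid.grid_shape} grid "
            f"({grid.n_patches} expected)"
        )
    ph, pw = grid.patch_size
    if patches.shape[1:] != (ph, pw):
        raise GridError(f"patch shape {patches.shape[1:]} != grid patch size {(ph, pw)}")
    rows, cols = grid.grid_shape
    full = (
        patches.reshape(rows, cols, ph, pw).transpose(0, 2, 1, 3).reshape(rows * ph, cols * pw)
    )
    h, w = original_shape if original_shape is not None else grid.original_shape
    if h > full.shape[0] or w > full.shape[1]:
        raise GridError(f"target shape {(h, w)} exceeds stitched extent {full.shape}")
    return full[:h, :w]


@dataclass
class PresenceRule:
    """Keep a block only if enough of it sits above an intensity floor.

    A block passes when the fraction of voxels brighter than
    ``intensity_threshold`` exceeds ``min_foreground_frac``.
    """

    intensity_threshold: float = 0.05
    min_foreground_frac: float = 0.01

    def __call__(self, block: np.ndarray) -> bool:
        frac = float(np.mean(block > self.intensity_threshold))
        return frac > self.min_foreground_frac


@dataclass
class SequenceBlock:
    data: np.ndarray  # (seq_len, ph, pw)
    origin: tuple[int, int, int]  # (z0, y0, x0) in the padded frame


def make_sequences(
    stack: ImageStack,
    seq_len: int = 31,
    patch_size=32,
    stride_z: int | None = None,
    presence_filter: PresenceRule | None = None,
) -> list[SequenceBlock]:
    """Cut a stack into (seq_len, ph, pw) blocks: sliding z-windows at
    ``stride_z`` (default: non-overlapping), laterally tiled via
    :func:`patchify`. Blocks failing the presence filter are discarded."""
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    z = data.shape[0]
    if seq_len > z:
        raise SizeError(f"seq_len {seq_len} exceeds stack depth {z}")
    if stride_z is None:
        stride_z = seq_len
    if stride_z < 1:
        raise SizeError("stride_z must be >= 1")
    _, grid = patchify(data[0], patch_size)
    blocks: list[SequenceBlock] = []
    for z0 in range(0, z - seq_len + 1, stride_z):
        window = data[z0 : z0 + seq_len]
        tiles = np.stack([patchify(s, patch_size)[0] for s in window], axis=1)
        # tiles: (n_patches, seq_len, ph, pw)
        for p_idx in range(grid.n_patches):
            block = tiles[p_idx]
            if presence_filter is not None and not presence_filter(block):
                continue
            oy, ox = grid.origins[p_idx]
            blocks.append(SequenceBlock(block, (z0, oy, ox)))
    return blocks
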