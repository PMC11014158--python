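"""Image-quality metrics and axial-elongation measurement.

PSNR and SSIM are the scalar quality scores used throughout the benchmark
tables; elongation quantifies the axial (z) stretching of a bead: the ratio
of the axial to the mean lateral full width at half maximum (FWHM) of the
intensity profile through the bead centre. An undistorted spherical bead has
ratio 1; refractive-index mismatch stretches it along z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.metrics import structural_similarity

from .errors import ShapeError, TruncationError
from .imgio import ImageStack


def psnr(ref: np.ndarray, test: np.ndarray, data_range: float = 1.0) -> float:
    """10*log10(data_range^2 / MSE); +inf when the images are identical."""
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if ref.shape != test.shape:
        raise ShapeError(f"shape mismatch: {ref.shape} vs {test.shape}")
    if data_range <= 0:
        raise ValueError("data_range must be > 0")
    mse = float(np.mean((ref - test) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(data_range**2 / mse))


def ssim(ref: np.ndarray, test: np.ndarray, data_range: float = 1.0) -> float:
    """Mean local SSIM with an 11-tap Gaussian window (sigma 1.5) and the
    standard stabilisation constants."""
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if ref.shape != test.shape:
        raise ShapeError(f"shape mismatch: {ref.shape} vs {test.shape}")
    return float(
        structural_similarity(
            ref,
            test,
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
        )
    )


@dataclass
class ElongationReport:
    axial_fwhm: float  # z-extent at half maximum, voxels
    lateral_fwhm: float  # mean of y- and x-extents, voxels
    ratio: float  # axial / lateral


def _profile_fwhm(profile: np.ndarray, peak_index: float) -> float:
    """FWHM of a 1-D profile around ``peak_index`` via linear interpolation
    of the half-maximum crossings; baseline is the profile minimum."""
    base = float(profile.min())
    # use the local maximum nearest the nominal centre as the peak
    i0 = int(round(peak_index))
    lo, hi = max(0, i0 - 2), min(len(profile), i0 + 3)
    i_peak = lo + int(np.argmax(profile[lo:hi]))
    peak = float(profile[i_peak])
    if peak <= base:
        raise TruncationError("no peak above baseline at the requested centre")
    level = base + 0.5 * (peak - base)

    def _cross(direction: int) -> float:
        i = i_peak
        while 0 <= i + direction < len(profile):
            j = i + direction
            if profile[j] < level:
                frac = (profile[i] - level) / (profile[i] - profile[j])
                return abs(i - i_peak) + frac
            i = j
        raise TruncationError("profile never falls below half maximum inside the stack")

    return _cross(-1) + _cross(+1)


def measure_elongation(stack: ImageStack | np.ndarray, center) -> ElongationReport:
    """FWHM along z, y, x through a (possibly fractional) bead centre.

    Profiles are sampled along each axis through the centre with linear
    interpolation; invariant to uniform intensity scaling.
    """
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack, dtype=np.float64)
    cz, cy, cx = (float(c) for c in center)
    nz, ny, nx = data.shape
    if not (0 <= cz < nz and 0 <= cy < ny and 0 <= cx < nx):
        raise ShapeError(f"center {center} outside stack {data.shape}")

    def _axis_profile(axis: int, extent: int):
        coords = np.empty((3, extent))
        coords[0], coords[1], coords[2] = cz, cy, cx
        coords[axis] = np.arange(extent)
        return ndi.map_coordinates(data, coords, order=1, mode="nearest")

    fz = _profile_fwhm(_axis_profile(0, nz), cz)
    fy = _profile_fwhm(_axis_profile(1, ny), cy)
    fx = _profile_fwhm(_axis_profile(2, nx), cx)
    lateral = 0.5 * (fy + fx)
    return ElongationReport(axial_fwhm=fz, lateral_fwhm=lateral, ratio=fz / lateral)
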