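"""Bead calibration phantoms and distortion-correction target synthesis.

Fluorescent microspheres (4 um diameter) embedded in agarose are the
calibration object for axial distortion: a perfect sphere that images as an
axially elongated blob reveals the z-stretch directly. This module

* simulates distorted/undistorted bead stack pairs with a known truth table
  (elongation modelled as axial scaling of the bead's Gaussian width, which
  keeps a closed-form truth for the FWHM-based elongation metric);
* reproduces the target-synthesis procedure used to build training data
  from real bead stacks: per-slice K-means segmentation, 3-D component
  joining, centre-slice detection, and re-rendering of each bead as an
  isotropic Gaussian-profile sphere ("a virtual bead image stack without
  distortion");
* assembles aligned (distorted, target) training corpora in either
  128x128-patch mode for the 2-D convolutional auto-encoder or
  31x32x32-sequence mode for the ConvLSTM auto-encoder.

Default geometry assumes 0.5 um voxels laterally, so a 4 um bead has a
4-voxel radius; the Gaussian profile uses sigma = radius / 2.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import scipy.ndimage as ndi
from sklearn.cluster import KMeans

from .errors import CoordinateError, DataError, PackingError, ParameterError, ShapeError
from .imgio import ImageStack, PresenceRule, make_sequences, patchify

_KMEANS_SPREAD_FLOOR = 0.02
_KMEANS_MAX_SAMPLES = 20000


@dataclass
class BeadPhantomSpec:
    volume_shape: tuple[int, int, int] = (64, 256, 256)  # (Z, Y, X)
    n_beads: int = 40
    radius_vox: float = 4.0  # lateral radius; 4 um diameter at 0.5 um voxels
    elongation: float = 4.0  # axial stretch factor >= 1
    peak_intensity: float = 0.8
    background: float = 0.05
    min_separation: float = 16.0  # pairwise centre distance, voxels
    seed: int = 0

    def __post_init__(self):
        if self.elongation < 1:
            raise ParameterError("elongation must be >= 1")
        if self.n_beads < 0 or self.radius_vox <= 0:
            raise ParameterError("n_beads must be >= 0 and radius_vox > 0")
        if not 0 <= self.background < self.peak_intensity <= 1:
            raise ParameterError("need 0 <= background < peak_intensity <= 1")

    @property
    def sigma_lateral(self) -> float:
        return self.radius_vox / 2.0


@dataclass
class BeadDetection:
    center: tuple[float, float, float]  # (z, y, x), fractional voxels
    center_slice: int
    lateral_radius_vox: float
    lateral_sigma_vox: float | None = None  # Gaussian width from lateral FWHM


def _render_gaussian(volume, center, sigma_zyx, amplitude, baseline):
    """Max-combine one Gaussian blob (baseline + amplitude * profile) into
    the volume, evaluated on a local 4-sigma window."""
    nz, ny, nx = volume.shape
    cz, cy, cx = center
    sz, sy, sx = sigma_zyx
    z0, z1 = max(0, int(cz - 4 * sz)), min(nz, int(cz + 4 * sz) + 2)
    y0, y1 = max(0, int(cy - 4 * sy)), min(ny, int(cy + 4 * sy) + 2)
    x0, x1 = max(0, int(cx - 4 * sx)), min(nx, int(cx + 4 * sx) + 2)
    z, y, x = np.ogrid[z0:z1, y0:y1, x0:x1]
    blob = baseline + amplitude * np.exp(
        -((z - cz) ** 2 / (2 * sz**2) + (y - cy) ** 2 / (2 * sy**2) + (x - cx) ** 2 / (2 * sx**2))
    )
    np.maximum(volume[z0:z1, y0:y1, x0:x1], blob, out=volume[z0:z1, y0:y1, x0:x1])


def simulate_bead_stack(spec: BeadPhantomSpec):
    """Simulate a distorted/ground-truth bead stack pair.

    Ground truth holds isotropic Gaussian-profile beads (sigma = radius/2);
    the distorted stack holds the same beads with axial sigma multiplied by
    ``spec.elongation``. Returns (distorted, ground_truth, truth_table).
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.volume_shape
    sig = spec.sigma_lateral
    margin_xy = 3.0 * sig + 1
    margin_z = 3.0 * sig * spec.elongation + 1
    if 2 * margin_z >= nz or 2 * margin_xy >= min(ny, nx):
        raise ParameterError(
            f"volume {spec.volume_shape} too small for elongation {spec.elongation}"
        )
    centers: list[tuple[float, float, float]] = []

    def _separated(c, p):
        # separation in the elongation-normalised metric, where beads are
        # round: an axial gap must be `elongation` times larger than a
        # lateral one to keep the distorted footprints from merging
        dz = (c[0] - p[0]) / spec.elongation
        return np.sqrt(dz**2 + (c[1] - p[1]) ** 2 + (c[2] - p[2]) ** 2) >= spec.min_separation

    for _ in range(spec.n_beads):
        for _attempt in range(1000):
            c = (
                rng.uniform(margin_z, nz - 1 - margin_z),
                rng.uniform(margin_xy, ny - 1 - margin_xy),
                rng.uniform(margin_xy, nx - 1 - margin_xy),
            )
            if all(_separated(c, p) for p in centers):
                centers.append(c)
                break
        else:
            raise PackingError(
                f"could not place bead {len(centers) + 1}/{spec.n_beads} "
                f"with min_separation {spec.min_separation}"
            )
    truth = np.full(spec.volume_shape, spec.background, dtype=np.float64)
    distorted = np.full(spec.volume_shape, spec.background, dtype=np.float64)
    table = []
    amp = spec.peak_intensity - spec.background
    for c in centers:
        _render_gaussian(truth, c, (sig, sig, sig), amp, spec.background)
        _render_gaussian(
            distorted, c, (sig * spec.elongation, sig, sig), amp, spec.background
        )
        table.append(
            BeadDetection(center=c, center_slice=int(round(c[0])), lateral_radius_vox=spec.radius_vox)
        )
    gt = ImageStack(np.clip(truth, 0, 1))
    dist = ImageStack(np.clip(distorted, 0, 1))
    return dist, gt, table


def kmeans_segment_slice(slice2d: np.ndarray) -> np.ndarray:
    """Two-cluster K-means on intensities; the brighter cluster is
    foreground. Slices with spread below a small floor yield an empty mask.

    In one dimension K-means assignment is thresholding at the midpoint of
    the two centroids, which is how the mask is materialised.
    """
    img = np.asarray(slice2d, dtype=np.float64)
    if img.ndim != 2:
        raise ShapeError("kmeans_segment_slice expects a 2-D slice")
    if np.ptp(img) < _KMEANS_SPREAD_FLOOR:
        return np.zeros(img.shape, dtype=np.uint8)
    flat = img.reshape(-1, 1)
    step = max(1, flat.shape[0] // _KMEANS_MAX_SAMPLES)
    sample = flat[::step]
    km = KMeans(n_clusters=2, n_init=3, random_state=0).fit(sample)
    midpoint = float(km.cluster_centers_.mean())
    return (img >= midpoint).astype(np.uint8)


def detect_beads(stack: ImageStack, min_voxels: int = 8) -> list[BeadDetection]:
    """Segment every slice, join masks into 3-D components (26-connectivity),
    and summarise each component as a bead detection.

    Centre is the intensity-weighted centroid; the centre slice is its
    rounded z; the lateral radius is the equivalent-circle radius of the
    component's largest cross-section. Small components are rejected.
    """
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    mask = np.stack([kmeans_segment_slice(s) for s in data])
    labels, n = ndi.label(mask, structure=np.ones((3, 3, 3)))
    detections = []
    for idx in range(1, n + 1):
        comp = labels == idx
        if comp.sum() < min_voxels:
            continue
        weights = np.where(comp, data, 0.0)
        cz, cy, cx = ndi.center_of_mass(weights)
        # the mask's axial extent is sensitive to per-slice thresholds when
        # other beads share the slice, which biases the z centroid; refine
        # cz by a quadratic fit around the axial intensity peak instead
        cz = _refine_axial_center(data, comp, cz, cy, cx)
        areas = comp.sum(axis=(1, 2))
        r_eq = float(np.sqrt(areas.max() / np.pi))
        detections.append(
            BeadDetection(
                center=(float(cz), float(cy), float(cx)),
                center_slice=int(round(cz)),
                lateral_radius_vox=r_eq,
                lateral_sigma_vox=_lateral_sigma(data, (cz, cy, cx)),
            )
        )
    return detections


def _refine_axial_center(data, comp, cz, cy, cx):
    """Sub-voxel axial centre from the z-profile through the lateral
    centroid: argmax within the component's z-extent plus a three-point
    quadratic (parabolic) refinement."""
    zs = np.nonzero(comp.any(axis=(1, 2)))[0]
    z0, z1 = int(zs.min()), int(zs.max()) + 1
    iy, ix = int(round(cy)), int(round(cx))
    profile = data[z0:z1, iy, ix]
    k = int(np.argmax(profile))
    z_peak = z0 + k
    if 0 < k < len(profile) - 1:
        a, b, c = profile[k - 1], profile[k], profile[k + 1]
        denom = a - 2 * b + c
        if denom < 0:  # strict local maximum
            z_peak = z0 + k + 0.5 * float((a - c) / denom)
    return float(z_peak)


def _lateral_sigma(data, center):
    """Gaussian width of the lateral profile through a bead centre,
    estimated as mean lateral FWHM / 2.355. Returns None when the profile
    is truncated (bead at the volume edge)."""
    from .errors import TruncationError as _TErr
    from .metrics import measure_elongation

    try:
        report = measure_elongation(data, center)
    except _TErr:
        return None
    return float(report.lateral_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))))


def render_target_stack(
    detections,
    volume_shape,
    profile_sigma_frac: float = 0.5,
    peak: float = 0.8,
    background: float = 0.05,
) -> ImageStack:
    """Render the undistorted target: one isotropic Gaussian-profile sphere
    per detection at (center_slice, y, x); overlaps combine by maximum.

    The profile width mirrors the bead's measured lateral width
    (``lateral_sigma_vox``) when the detection carries one, so the target
    differs from the original only along z — corrected from elongation,
    unchanged laterally. Detections without a width estimate fall back to
    ``profile_sigma_frac * lateral_radius_vox``.
    """
    nz, ny, nx = volume_shape
    vol = np.full(volume_shape, float(background), dtype=np.float64)
    for det in detections:
        cz, cy, cx = det.center_slice, det.center[1], det.center[2]
        if not (0 <= cz < nz and 0 <= cy < ny and 0 <= cx < nx):
            raise CoordinateError(f"detection at {det.center} outside volume {volume_shape}")
        sigma = det.lateral_sigma_vox
        if sigma is None:
            sigma = profile_sigma_frac * det.lateral_radius_vox
        _render_gaussian(vol, (float(cz), cy, cx), (sigma, sigma, sigma), peak - background, background)
    return ImageStack(np.clip(vol, 0, 1))


@dataclass
class DistortionCorpus:
    """Aligned (distorted input, undistorted target) training blocks."""

    inputs: np.ndarray  # (n, ph, pw) or (n, seq, ph, pw)
    targets: np.ndarray
    origins: list
    mode: str
    manifest: dict = field(default_factory=dict)

    @property
    def n_blocks(self):
        return self.inputs.shape[0]


_DEFAULT_PRESENCE = PresenceRule()


def build_distortion_corpus(
    distorted: ImageStack,
    target: ImageStack,
    mode: str = "patch128",
    presence: PresenceRule | None = _DEFAULT_PRESENCE,
    seed: int = 0,
) -> DistortionCorpus:
    """Cut aligned training blocks out of a (distorted, target) stack pair.

    ``patch128``: per-slice 128x128 patches; ``seq31x32``: 31-slice windows
    of 32x32 patches. Presence is judged on the distorted input block (it has
    the wider axial footprint), discarding background-only regions that would
    otherwise drive the network toward flat gray output.
    """
    if distorted.shape != target.shape:
        raise ShapeError(f"stack shapes differ: {distorted.shape} vs {target.shape}")
    inputs, targets, origins = [], [], []
    if mode == "patch128":
        for z in range(distorted.n_slices):
            pin, grid = patchify(distorted.data[z], 128)
            ptg, _ = patchify(target.data[z], 128)
            for p_idx in range(grid.n_patches):
                if presence is not None and not presence(pin[p_idx]):
                    continue
                inputs.append(pin[p_idx])
                targets.append(ptg[p_idx])
                origins.append((z, *grid.origins[p_idx]))
    elif mode == "seq31x32":
        bin_ = make_sequences(distorted, seq_len=31, patch_size=32, presence_filter=None)
        btg = make_sequences(target, seq_len=31, patch_size=32, presence_filter=None)
        for bi, bt in zip(bin_, btg):
            if presence is not None and not presence(bi.data):
                continue
            inputs.append(bi.data)
            targets.append(bt.data)
            origins.append(bi.origin)
    else:
        raise ParameterError(f"unknown corpus mode '{mode}'")
    if not inputs:
        raise DataError("presence filter removed every block; no corpus")
    manifest = {
        "mode": mode,
        "seed": seed,
        "presence": asdict(presence) if presence is not None else None,
        "n_blocks": len(inputs),
        "volume_shape": list(distorted.shape),
    }
    return DistortionCorpus(
        np.stack(inputs).astype(np.float32),
        np.stack(targets).astype(np.float32),
        origins,
        mode,
        manifest,
    )
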