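# Methods

This note documents the models implemented in `lsfm-restore`, the choices
made where the design was genuinely open, the synthetic data the evaluation
rests on, and the limitations of both.

## Image model and conventions

Stacks are grids indexed `(z, y, x)`, held as float32 in [0, 1]; integer
TIFF data is scaled by `2^depth − 1` on read and re-quantised
(round-half-away-from-zero) on write, making read/write round trips exact.
Bounded inputs are assumed throughout because both training losses used
(MSE and binary cross entropy) presuppose them. Slices are processed as
non-overlapping patches with edge-replication padding; stitching is the
exact left inverse of extraction. Overlapping patches were not needed: the
convolutional models show no visible seam artefacts at patch borders.

## Noise model

The camera is modelled as mixed Poisson–Gaussian:
`z = Poisson(g·y)/g + N(0, σ²) + offset`, clipped to [0, 1].
Dividing the Poisson draw by the gain `g` (photons per unit normalised
intensity) keeps the clean signal as the mean, giving the affine variance
law `Var(z) = y/g + σ²`. Defaults are `g = 100`, `σ = 0.02`, recorded in
every corpus manifest. Clipping introduces a small bias only where
`y ± 3·std` crosses the range bounds; the default study levels avoid that
regime.

The variance-law check uses a deliberate experimental design: one *dark
frame* (`y = 0`, lifted by a constant offset so the Gaussian component
cannot clip) pins the signal-independent intercept directly — the standard
camera-calibration practice — and the regression is weighted least squares
with weights `1/v̂²`, since the sampling error of a variance estimate is
proportional to the variance itself. With ordinary least squares over
bright levels only, the intercept (4·10⁻⁴) is statistically unresolvable at
10⁴ draws per level.

## Richardson–Lucy deconvolution

The update implemented is the flux-preserving form

```
O_{n+1} = (1 − γ) · O_n · [(D / (H ⊛ O_n + ε)) ⊛ Ĥ] + γ · (R ⊛ O_n)
```

with Ĥ the spatially flipped kernel, `R` a normalised box filter
(default 3×3), `ε = 1e−12` a division guard, and reflective boundaries for
all convolutions — under which a normalised kernel conserves total flux
(verified to < 1% over 50 iterations at γ = 0; in practice the drift is at
floating-point level). γ = 1 returns the smoothed iterate exactly; γ = 0 is
textbook RL, pinned in tests against a nested-loop oracle to 1e−10.
Defaults `n_iters = 50`, `γ = 0.01` are package choices, logged per run.
Monotone likelihood ascent is *not* asserted for the regularised variant;
the contract is restoration gain on a known-blur fixture.

The PSF is parametric (anisotropic Gaussian on an odd, centred grid,
normalised to unit mass) or loaded from a measured kernel TIFF. A full
optical image-formation model is out of scope; the RL machinery only
requires a known `H`. Direct Fourier inversion `O = F⁻¹[F(D)/F(H)]` is
included solely as a documented anti-example; a test demonstrates its noise
amplification (≥ 10 dB worse than RL under 0.1% additive noise).

## Contrast

CLAHE (tile-wise histogram equalisation with clipped histograms and
bilinear blending between tile mappings). The stage owns parameters,
normalisation and determinism and delegates the equalisation to
scikit-image's implementation of the same algorithm. Defaults:
`clip_limit = 0.01`, 8×8 tiles, 256 bins. Constant slices are returned
unchanged (there is no contrast to redistribute).

## Denoising auto-encoder

Encoder `conv(f1,5×5) → BN → pool → conv(f2,3×3) → spatial dropout → pool →
conv(f3,3×3) → BN → pool` (128 → 64 → 32 → 16); decoder `conv(f3) → BN →
upsample → tconv(f2, stride 2) → BN → conv(f1) → BN → upsample →
conv(1,5×5) → sigmoid` (16 → 32 → 64 → 128). The printed decoder has two
upsamplings for three encoder poolings; assigning stride 2 to the
transposed convolution is the only spatial bookkeeping that returns the
output to 128×128, and it is what this package implements. The skip
connection adds the encoder's second activation (post-dropout, pre-pool —
the only tensor with matching 64×64×f2 shape) elementwise onto the
transposed-convolution output. Hidden activations are ReLU, the output is a
sigmoid (matching [0, 1] targets under MSE); spatial dropout rate 0.2.

Two named profiles:

| profile | filters | lr | epochs | batch |
|---|---|---|---|---|
| reference | 256/512/1024 | 1e−6 | 200 | 8 |
| scaled-down (CI) | 32/64/128 | 1e−3 | 30 | 8 |

The scaled-down profile raises the learning rate to converge within the
reduced budget; it is the default for the CPU-scale studies. Training is
Adam on MSE, seeded end to end. All three trainers in the package (DAE,
conv-AE, ConvLSTM-AE) initialise the output layer's bias to the logit of
the mean target intensity: fluorescence targets are mostly dark, and a
zero-initialised sigmoid output starts at 0.5 — deep in the wrong
saturation region — so short training budgets would otherwise be spent
relearning the background level (on the standard denoising corpus this
prior initialisation lowers the epoch-8 training loss by more than an
order of magnitude). two runs with the same seed produce
bit-identical weights. Model files carry the weights, a JSON manifest
(corpus parameters, full loss curve), and a SHA-256 fingerprint of the
architecture config; loading onto a mismatched config is refused.

## Classical baselines

`{bilateral, median, mean, total_variation, wavelet_bayes,
wavelet_visushrink}` via scikit-image/scipy with 3×3 windows, TV weight 0.1
and wavelet defaults, all logged. The benchmark reports mean, standard
error of the mean, and standard deviation of PSNR/SSIM over held-out
images — both dispersion columns are emitted because "±" in comparison
tables is ambiguous between the two. The noisy input is always reported as
the floor row.

## Metrics

PSNR uses `data_range = 1` on the internal float scale. SSIM is the
Gaussian-window (σ = 1.5, 11 taps) variant with the standard constants.
Axial elongation is estimated as FWHM ratio: intensity profiles along each
axis through the (fractional) bead centre are sampled with linear
interpolation; the FWHM is found by walking from the peak to the first
half-maximum crossing on each side (baseline = profile minimum, so the
measure is invariant to uniform intensity scaling); the ratio is axial FWHM
over the mean of the two lateral FWHMs. Profiles that never fall below half
maximum raise a truncation error rather than returning a guess.

## Bead phantom and target synthesis

The simulator places `n` non-overlapping Gaussian-profile beads (lateral
σ = radius/2; default radius 4 voxels ≈ a 4 µm bead at 0.5 µm lateral
voxels) at seeded random positions with a minimum pairwise separation —
enforced in the elongation-normalised metric `(Δz/e, Δy, Δx)`, where the
distorted footprints are round, so that two beads can never merge into one
connected component however they are placed — and
emits two stacks sharing centres and intensities: isotropic ground truth,
and a distorted stack whose axial σ is multiplied by the elongation factor
(reported range for the instrument class: ≈ 1.8 at 6× magnification to
≈ 10 at 2×; default 4). Modelling distortion as axial width scaling (rather
than coordinate resampling) keeps a closed-form truth for the FWHM metric.

Target synthesis follows the calibration procedure: per-slice 2-cluster
K-means on intensities (in 1-D, K-means assignment *is* thresholding at the
centroid midpoint, which is how the mask is materialised; a spread floor of
0.02 returns an empty mask for featureless slices), 3-D joining of
per-slice masks with 26-connectivity, rejection of components under
8 voxels, intensity-weighted centroids, and re-rendering of each bead as an
isotropic Gaussian sphere at its centre slice. The axial centre is refined
by a three-point parabolic fit around the z-intensity peak through the
lateral centroid: the mask-based z centroid is biased whenever other beads
share a slice (the per-slice threshold then truncates the dim axial tails
asymmetrically), whereas the peak position is insensitive to mask shape. The rendered width mirrors
the bead's *measured* lateral width (σ̂ = lateral FWHM / 2.355, unbiased
for a Gaussian bead) rather than a fixed fraction of the segmentation-mask
radius: the target must differ from the input only along z, and a
mask-derived width systematically under-renders the lateral profile
(the mask radius depends on the K-means threshold, not the bead). Detection
centres carry ≈ 2 voxels of z jitter from per-slice thresholds; the
detection contract is 2-voxel accuracy at peak/background ≥ 5.

## Distortion-correction networks

*Two-layer conv auto-encoder*: `conv(filters, 3×3, ReLU) → tconv(1, 3×3) →
sigmoid` on 128×128 patches; RMSprop on binary cross entropy. Profiles:
reference 1024 filters / 100 epochs / lr 1e−3; scaled-down 64 filters /
20 epochs / lr 3e−3 (higher rate for the shorter budget, as in the DAE
profile). *ConvLSTM auto-encoder*: `CLSTM(16) → CLSTM(32) → CLSTM(32) →
CLSTM(16) → conv3D(1, 3×3×3) → sigmoid` on 31-slice sequences of 32×32
patches, every recurrent layer emitting full sequences (the only reading
under which the output shape 31×32×32×1 is reachable); Adam on MSE,
reference lr 1e−4, batch 8.

Training uses presence-filtered blocks only (keep a block if > 1% of its
voxels exceed intensity 0.05): a mostly-black corpus drives either model
toward flat gray output (mean collapse). The output/target variance ratio
is recorded in every training manifest as a contrast-loss monitor rather
than silently accepted.

Stack-level correction decomposes per the model mode (per-slice patches, or
non-overlapping 31-slice z-windows with one final overlapping window whose
values win in the overlap, so any stack depth ≥ 31 is covered exactly).

**Known structural limitation of the per-slice model.** On a bead phantom,
slices of distorted and undistorted beads form the same one-parameter
family (a blob of fixed lateral width and varying amplitude), so a 2-D
per-slice corrector applies the same axial re-profiling to both stacks:
corrected ratio on a distorted stack equals elongation × corrected ratio on
an undistorted one, exactly. Consequently a per-slice model that
meaningfully reduces elongation necessarily alters undistorted stacks by
the same factor, and a "no-harm within 15%" requirement caps its achievable
correction at ~15%. The measured studies match this identity at every
training setting probed. This is the structural reason a z-aware model
(the ConvLSTM, which sees the 31-slice context and can distinguish an
elongated profile from an in-focus one) is the appropriate architecture for
axial correction; the 2-D model is retained as the simpler, faster
calibration check.

## Study conditions and problem sizes

The standard evaluation (shared by the test suite and
`scripts/acceptance.py`) uses: noise regression over 5 levels × 10⁴ draws;
a 256×256 phantom blurred with a σ = 2 Gaussian PSF and restored with 50 RL
iterations (γ = 0.01); a denoising corpus of 300 synthetic 128×128 images
(gain 100, σ = 0.02, ~243/57 train/test split at the 1000:237 reference
ratio) with the scaled-down DAE; a 40-bead, elongation-4, 64×256×256
calibration stack; and distortion training on that stack with evaluation on
a second, independently seeded stack (held-out beads). The ConvLSTM study —
recurrent training is by far the most expensive — runs on a reduced
62×128×128 volume with 10 beads (two full 31-slice windows deep) at a
smoke-level epoch budget. These sizes are the
package's chosen single-CPU scale; the reference network profiles are
provided for larger runs.

## What the synthetic data does and does not show

The generators emulate bright somata and dim filaments on dark background,
shot + read noise, known Gaussian blur, and axially stretched Gaussian
beads. They do not emulate: stripe artefacts, depth-dependent or spatially
varying PSFs, autofluorescent background structure, bead clusters/doublets,
saturation, or the intensity statistics of any particular instrument.
Passing studies therefore demonstrate that each algorithm performs its
function under its own model assumptions — not calibrated performance on
real microscope data, whose corruption parameters are not reproduced here.

## Determinism and numerics

All randomness flows through seeded NumPy generators (corpus shuffles,
weight init, dropout); training is bit-for-bit reproducible on the same
platform. Networks run in float32; gradient correctness of every layer
(including the ConvLSTM's backpropagation through time) is pinned by
central-difference checks in float64. Division guards: RL denominator
ε = 1e−12; BCE predictions clipped to [1e−7, 1 − 1e−7]; batch-norm
ε = 1e−5 with momentum 0.9 running statistics.
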