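"""Reproducible study runners for the package's standard evaluation suite.

Each function builds its inputs from the synthetic generators, runs one
stage of the pipeline at the standard study conditions, and returns a flat
dict of measured quantities (keys starting with ``_`` carry non-scalar
artefacts — models, stacks, report tables — for callers that want them).
The default seeds and problem sizes are the package's standard evaluation
conditions; scaled-down network profiles keep every study tractable on a
single CPU.
"""

from __future__ import annotations

import numpy as np

from .baselines import BaselineSpec, available_baselines, benchmark
from .beads import (
    BeadPhantomSpec,
    build_distortion_corpus,
    detect_beads,
    render_target_stack,
    simulate_bead_stack,
)
from .dae import DAEConfig, build_dae, denoise_slices, train_dae
from .deconv import RLConfig, convolve_observe, gaussian_psf, rl_deconvolve
from .distortion import (
    ConvAEConfig,
    ConvLSTMConfig,
    build_conv_ae,
    build_convlstm_ae,
    correct_stack,
    train_conv_ae,
    train_convlstm_ae,
)
from .errors import TruncationError
from .metrics import measure_elongation, psnr
from .noise import NoiseParams, build_pairs, corrupt, synth_clean_image


def noise_variance_study(seed: int = 123, gain: float = 100.0, sigma: float = 0.02,
                         levels=(0.0, 0.1, 0.2, 0.3, 0.4), offset: float = 0.3,
                         n_draws: int = 10_000) -> dict:
    """Regress the corruption variance onto clean intensity.

    The mixed Poisson-Gaussian model predicts Var(z) = y/gain + sigma^2
    independent of the offset. The design includes a dark frame (y = 0,
    lifted by a constant offset so nothing clips) — the standard way to pin
    the signal-independent component — and the fit is weighted least squares
    with weights 1/v^2, since the sampling error of a variance estimate
    scales with the variance itself."""
    x = np.asarray(levels, dtype=float)
    variances = []
    for i, y in enumerate(levels):
        params = NoiseParams(gain, sigma, offset=offset, seed=seed + i)
        out = corrupt(np.full((1, 1, n_draws), y), params)
        variances.append(float(np.var(out)))
    v = np.asarray(variances)
    w = 1.0 / v**2
    design = np.vstack([x, np.ones_like(x)]).T
    slope, intercept = np.linalg.solve(design.T @ (w[:, None] * design), design.T @ (w * v))
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "slope_rel_err": abs(slope - 1.0 / gain) * gain,
        "intercept_rel_err": abs(intercept - sigma**2) / sigma**2,
        "n": len(levels) * n_draws,
    }


def deconvolution_study(seed: int = 7, shape=(256, 256), psf_sigma: float = 2.0,
                        psf_size: int = 21, n_iters: int = 50, gamma: float = 0.01) -> dict:
    """Blur a synthetic phantom with a known Gaussian PSF and restore it.

    Reports the PSNR gain of the flux-preserving RL restoration over the
    blurred input, and the worst relative total-intensity drift across
    iterations of the unregularised (gamma = 0) run."""
    clean = synth_clean_image(shape, seed=seed)
    psf = gaussian_psf(psf_sigma, psf_sigma, psf_size)
    blurred = convolve_observe(clean, psf)
    restored = rl_deconvolve(blurred, psf, RLConfig(n_iters=n_iters, gamma=gamma))
    _, flux = rl_deconvolve(blurred, psf, RLConfig(n_iters=n_iters, gamma=0.0), return_flux=True)
    log = np.asarray(flux[0])
    return {
        "psnr_blurred": psnr(clean, blurred),
        "psnr_restored": psnr(clean, np.clip(restored, 0, 1)),
        "psnr_gain_db": psnr(clean, np.clip(restored, 0, 1)) - psnr(clean, blurred),
        "flux_drift_pct": float(100 * np.abs(log - log[0]).max() / log[0]),
        "n": int(np.prod(shape)),
    }


def denoising_study(seed: int = 11, n_images: int = 300, gain: float = 100.0,
                    sigma: float = 0.02, epochs: int = 30, with_baselines: bool = True) -> dict:
    """Train the scaled-down denoising auto-encoder on a synthetic corpus.

    300 clean 128x128 fluorescence-like images are corrupted (gain 100,
    sigma 0.02) and split at the standard ratio; the CI-profile DAE
    (filters 32/64/128, lr 1e-3) is trained and scored on the held-out
    pairs against the classical baselines."""
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_images)
    images = [
        synth_clean_image((128, 128), n_cells=4, cell_radius_range=(3, 9), seed=int(s))
        for s in child_seeds
    ]
    params = NoiseParams(gain, sigma, seed=seed)
    corpus = build_pairs(images, params, patch_size=128)
    config = DAEConfig.ci_profile(seed=seed, epochs=epochs)
    model = train_dae(build_dae(config), corpus, config)
    denoised = denoise_slices(corpus.noisy_test, model)
    psnr_noisy = float(np.mean([psnr(c, x) for c, x in zip(corpus.clean_test, corpus.noisy_test)]))
    psnr_denoised = float(np.mean([psnr(c, x) for c, x in zip(corpus.clean_test, denoised)]))
    result = {
        "psnr_noisy": psnr_noisy,
        "psnr_denoised": psnr_denoised,
        "psnr_gain_db": psnr_denoised - psnr_noisy,
        "n": corpus.n_test,
        "_model": model,
        "_corpus": corpus,
    }
    if with_baselines:
        specs = [BaselineSpec(name) for name in available_baselines()]
        report = benchmark(corpus, specs, dae_model=model)
        by_method = report.set_index("method")["psnr_mean"]
        result["psnr_median_filter"] = float(by_method["median"])
        result["psnr_best_classical"] = float(by_method.drop(["noisy", "dae"]).max())
        result["best_classical_method"] = str(by_method.drop(["noisy", "dae"]).idxmax())
        result["_report"] = report
    return result


def _match_recall(truth_table, detections, tol: float = 2.0) -> float:
    if not truth_table:
        return float("nan")
    found = np.array([d.center for d in detections]) if detections else np.empty((0, 3))
    hits = 0
    for det in truth_table:
        if found.size and np.min(np.linalg.norm(found - np.asarray(det.center), axis=1)) <= tol:
            hits += 1
    return hits / len(truth_table)


def bead_synthesis_study(seed: int = 3, spec: BeadPhantomSpec | None = None) -> dict:
    """Simulate the standard 40-bead elongation-4 stack, detect beads, and
    render the isotropic target; reports detection recall (2-voxel match)
    and the elongation ratios of distorted, ground-truth and rendered beads."""
    spec = spec or BeadPhantomSpec(seed=seed)
    distorted, truth, table = simulate_bead_stack(spec)
    detections = detect_beads(distorted)
    target = render_target_stack(
        detections, spec.volume_shape, peak=spec.peak_intensity, background=spec.background
    )

    def _ratios(stack, centers):
        out = []
        for c in centers:
            try:
                out.append(measure_elongation(stack, c).ratio)
            except TruncationError:
                pass
        return np.asarray(out)

    truth_centers = [d.center for d in table]
    det_centers = [d.center for d in detections]
    target_ratios = _ratios(target, det_centers)
    return {
        "recall": _match_recall(table, detections),
        "n_detected": len(detections),
        "distorted_ratio_mean": float(_ratios(distorted, truth_centers).mean()),
        "ground_truth_ratio_mean": float(_ratios(truth, truth_centers).mean()),
        "target_ratio_mean": float(target_ratios.mean()),
        "target_ratio_min": float(target_ratios.min()),
        "target_ratio_max": float(target_ratios.max()),
        "n": spec.n_beads,
        "_distorted": distorted,
        "_truth": truth,
        "_table": table,
        "_detections": detections,
        "_target": target,
        "_spec": spec,
    }


def _paired_ratios(reference_stack, test_stack, table):
    ref, test = [], []
    for det in table:
        try:
            r = measure_elongation(reference_stack, det.center).ratio
            t = measure_elongation(test_stack, det.center).ratio
        except TruncationError:
            continue
        ref.append(r)
        test.append(t)
    return np.asarray(ref), np.asarray(test)


def distortion_conv_study(seed: int = 3, eval_seed: int = 4, filters: int = 64,
                          epochs: int = 20, lr: float | None = None) -> dict:
    """Train the two-layer conv auto-encoder on the standard bead corpus and
    measure elongation recovery on a held-out simulated stack, plus the
    no-harm shift when correcting an undistorted stack."""
    synth = bead_synthesis_study(seed=seed)
    corpus = build_distortion_corpus(synth["_distorted"], synth["_target"], "patch128")
    overrides = dict(filters=filters, epochs=epochs, seed=seed)
    if lr is not None:
        overrides["lr"] = lr
    config = ConvAEConfig.ci_profile(**overrides)
    model = train_conv_ae(build_conv_ae(config), corpus, config)
    spec_b = BeadPhantomSpec(seed=eval_seed)
    dist_b, truth_b, table_b = simulate_bead_stack(spec_b)
    corrected = correct_stack(dist_b, model)
    rd, rc = _paired_ratios(dist_b, corrected, table_b)
    truth_corr = correct_stack(truth_b, model)
    r0, r1 = _paired_ratios(truth_b, truth_corr, table_b)
    return {
        "distorted_ratio_mean": float(rd.mean()),
        "corrected_ratio_mean": float(rc.mean()),
        "frac_improved": float(np.mean(np.abs(rc - 1) < np.abs(rd - 1))),
        "noharm_shift_mean": float(np.mean(np.abs(r1 - r0))),
        "noharm_shift_max": float(np.max(np.abs(r1 - r0))) if r0.size else float("nan"),
        "n_measured": int(rd.size),
        "variance_ratio": model.manifest["output_target_variance_ratio"],
        "n": spec_b.n_beads,
        "_model": model,
    }


def distortion_lstm_study(seed: int = 3, eval_seed: int = 4, epochs: int = 5,
                          spec: BeadPhantomSpec | None = None) -> dict:
    """Same recovery measurement for the ConvLSTM auto-encoder at the
    31x32x32 sequence scale (smoke-level training budget).

    Recurrent training is by far the most expensive study, so it runs on a
    reduced calibration volume (62x128x128, 10 beads) — two full 31-slice
    windows deep, enough blocks for a few dozen gradient steps."""
    spec = spec or BeadPhantomSpec(volume_shape=(62, 128, 128), n_beads=10, seed=seed)
    synth = bead_synthesis_study(seed=seed, spec=spec)
    corpus = build_distortion_corpus(synth["_distorted"], synth["_target"], "seq31x32")
    config = ConvLSTMConfig.ci_profile(seed=seed, epochs=epochs)
    model = train_convlstm_ae(build_convlstm_ae(config), corpus, config)
    spec_b = BeadPhantomSpec(
        volume_shape=spec.volume_shape, n_beads=spec.n_beads, elongation=spec.elongation,
        seed=eval_seed,
    )
    dist_b, _, table_b = simulate_bead_stack(spec_b)
    corrected = correct_stack(dist_b, model)
    rd, rc = _paired_ratios(dist_b, corrected, table_b)
    return {
        "distorted_ratio_mean": float(rd.mean()),
        "corrected_ratio_mean": float(rc.mean()),
        "frac_improved": float(np.mean(np.abs(rc - 1) < np.abs(rd - 1))),
        "n_measured": int(rd.size),
        "variance_ratio": model.manifest["output_target_variance_ratio"],
        "n": spec_b.n_beads,
        "_model": model,
    }
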