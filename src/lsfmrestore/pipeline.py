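"""End-to-end slice-by-slice restoration pipeline.

Stages run in a fixed order — deblur (RL deconvolution), CLAHE, denoise
(trained DAE) — each applied slice by slice, followed optionally by 3-D
distortion correction on the assembled stack. Every stage is independent
and can be bypassed without affecting the others; the run manifest records
all configs, seeds, package version, and (when a ground-truth reference is
supplied) the PSNR against the reference after every enabled stage.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .contrast import ClaheConfig, enhance_stack
from .dae import DAEConfig, TrainedModel, denoise_stack, load_trained_dae
from .deconv import RLConfig, gaussian_psf, load_psf, rl_deconvolve
from .distortion import (
    ConvAEConfig,
    ConvLSTMConfig,
    correct_stack,
    load_trained_conv_ae,
    load_trained_convlstm_ae,
)
from .errors import ParameterError
from .imgio import ImageStack, read_stack, write_stack
from .metrics import psnr

STAGE_ORDER = ("deblur", "clahe", "denoise", "distortion")


@dataclass
class DeblurStage:
    psf_sigma: tuple[float, float] = (2.0, 2.0)
    psf_size: int = 21
    psf_file: str | None = None
    rl: RLConfig = field(default_factory=RLConfig)


@dataclass
class DenoiseStage:
    model_path: str = ""
    config: DAEConfig = field(default_factory=DAEConfig.ci_profile)


@dataclass
class DistortionStage:
    model_path: str = ""
    mode: str = "conv"  # "conv" | "lstm"
    conv_config: ConvAEConfig = field(default_factory=ConvAEConfig.ci_profile)
    lstm_config: ConvLSTMConfig = field(default_factory=ConvLSTMConfig.ci_profile)


@dataclass
class PipelineConfig:
    deblur: DeblurStage | None = None
    clahe: ClaheConfig | None = None
    denoise: DenoiseStage | None = None
    distortion: DistortionStage | None = None
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(seed=raw.get("seed", 0), out_dir=raw.get("out_dir"))
        if "deblur" in raw:
            section = dict(raw["deblur"] or {})
            rl = RLConfig(**section.pop("rl", {}))
            if "psf_sigma" in section:
                section["psf_sigma"] = tuple(section["psf_sigma"])
            cfg.deblur = DeblurStage(rl=rl, **section)
        if "clahe" in raw:
            section = dict(raw["clahe"] or {})
            if "tile_grid" in section:
                section["tile_grid"] = tuple(section["tile_grid"])
            cfg.clahe = ClaheConfig(**section)
        if "denoise" in raw:
            section = dict(raw["denoise"] or {})
            dae_cfg = section.pop("config", {})
            if "filters" in dae_cfg:
                dae_cfg["filters"] = tuple(dae_cfg["filters"])
            cfg.denoise = DenoiseStage(config=DAEConfig(**dae_cfg) if dae_cfg else DAEConfig.ci_profile(), **section)
        if "distortion" in raw:
            cfg.distortion = DistortionStage(**(raw["distortion"] or {}))
        return cfg


def _load_denoise_model(stage: DenoiseStage) -> TrainedModel:
    if not stage.model_path or not Path(stage.model_path).exists():
        raise ParameterError(f"denoise stage enabled but model not found: '{stage.model_path}'")
    return load_trained_dae(stage.model_path, stage.config)


def _load_distortion_model(stage: DistortionStage) -> TrainedModel:
    if not stage.model_path or not Path(stage.model_path).exists():
        raise ParameterError(f"distortion stage enabled but model not found: '{stage.model_path}'")
    if stage.mode == "conv":
        return load_trained_conv_ae(stage.model_path, stage.conv_config)
    if stage.mode == "lstm":
        return load_trained_convlstm_ae(stage.model_path, stage.lstm_config)
    raise ParameterError(f"unknown distortion mode '{stage.mode}'")


def run_pipeline(
    stack: ImageStack | str,
    config: PipelineConfig,
    reference: ImageStack | None = None,
):
    """Run the enabled stages in fixed order; returns (stack, manifest)."""
    if not isinstance(stack, ImageStack):
        stack = read_stack(stack)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
        "configs": {},
    }

    def _record(name, result):
        entry = {"stage": name}
        if reference is not None:
            entry["psnr_vs_reference"] = psnr(reference.data, result.data)
        manifest["stages"].append(entry)

    if reference is not None:
        manifest["input_psnr_vs_reference"] = psnr(reference.data, stack.data)

    for name in STAGE_ORDER:
        stage = getattr(config, name)
        if stage is None:
            continue
        if name == "deblur":
            psf = (
                load_psf(stage.psf_file)
                if stage.psf_file
                else gaussian_psf(*stage.psf_sigma, stage.psf_size)
            )
            stack = rl_deconvolve(stack, psf, stage.rl)
            manifest["configs"]["deblur"] = {"psf": psf.params, "rl": asdict(stage.rl)}
        elif name == "clahe":
            stack = enhance_stack(stack, stage)
            manifest["configs"]["clahe"] = asdict(stage)
        elif name == "denoise":
            model = _load_denoise_model(stage)
            stack = denoise_stack(stack, model)
            manifest["configs"]["denoise"] = {
                "model": stage.model_path,
                "fingerprint": model.fingerprint,
            }
        elif name == "distortion":
            model = _load_distortion_model(stage)
            stack = correct_stack(stack, model)
            manifest["configs"]["distortion"] = {
                "model": stage.model_path,
                "mode": stage.mode,
                "fingerprint": model.fingerprint,
            }
        _record(name, stack)

    if config.out_dir:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_stack(stack, out_dir / "restored.tif")
        import json

        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=float)
    return stack, manifest
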