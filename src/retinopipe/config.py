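"""YAML-backed configuration for the full pipeline.

One file, one section per stage::

    simulate:   {n_per_class: 30, size: 64, seed: 0, ...}
    preprocess: {denoise: true, diffusion: true, enhance: false, ...}
    hho:        {ps: 15, tm: 50}
    optics:     {min_pts: 5, eps: 0.08, ...}
    features:   {dark_k: 6.0, ...}
    ensemble:   {n_members: 3, epochs: 15, scale: 0.125, ...}
    severity:   {}
    evaluate:   {test_fraction: 0.25}

Unknown keys raise immediately so typos do not silently fall back to
defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .ensemble import EnsembleConfig
from .features import CandidateParams
from .preprocessing import DenoiseParams, DiffusionParams
from .segmentation import OpticsParams

__all__ = ["SimulateConfig", "PreprocessStageConfig", "PipelineConfig", "load_config"]


@dataclass
class SimulateConfig:
    n_per_class: int = 10
    size: int = 64
    seed: int = 0
    vessel_depth: int = 5
    noise_density: float = 0.01
    illumination_strength: float = 0.3
    blur_sigma: float = 0.5
    out_dir: str | None = None


@dataclass
class PreprocessStageConfig:
    denoise: bool = True
    diffusion: bool = True
    enhance: bool = False   # HHO search per image; enable explicitly
    denoise_params: DenoiseParams = field(default_factory=DenoiseParams)
    diffusion_params: DiffusionParams = field(default_factory=DiffusionParams)
    hho_ps: int = 15
    hho_tm: int = 50


@dataclass
class EvaluateConfig:
    test_fraction: float = 0.25
    out_dir: str = "results"


@dataclass
class PipelineConfig:
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessStageConfig = field(default_factory=PreprocessStageConfig)
    optics: OpticsParams = field(default_factory=OpticsParams)
    features: CandidateParams = field(default_factory=CandidateParams)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    evaluate: EvaluateConfig = field(default_factory=EvaluateConfig)
    run_preprocess: bool = False     # full per-image preprocessing is costly
    run_segmentation: bool = True    # OPTICS segmentation + lesion counting
    seed: int = 0


def _apply(obj, overrides: dict, section: str):
    valid = {f.name for f in dataclasses.fields(obj)}
    for key, value in overrides.items():
        if key not in valid:
            raise KeyError(f"unknown key {key!r} in config section {section!r}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            _apply(current, value, f"{section}.{key}")
        else:
            setattr(obj, key, value)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Build a config from defaults, an optional YAML file, then overrides."""
    cfg = PipelineConfig()
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        for section, vals in overrides.items():
            data.setdefault(section, {}).update(vals)
    top_level = {f.name: f for f in dataclasses.fields(cfg)}
    for section, vals in data.items():
        if section == "hho":  # convenience alias for preprocess HHO budget
            _apply(cfg.preprocess, {f"hho_{k}": v for k, v in vals.items()}, "hho")
            continue
        if section not in top_level:
            raise KeyError(f"unknown config section {section!r}")
        target = getattr(cfg, section)
        if dataclasses.is_dataclass(target) and isinstance(vals, dict):
            _apply(target, vals, section)
        else:
            setattr(cfg, section, vals)
    return cfg
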