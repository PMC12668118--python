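"""Strict YAML pipeline configuration."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .synthcohort import SyntheticConfig

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    seed: int
    out_dir: str = "pipeline_out"
    log_level: str = "INFO"
    # inputs; when absent a synthetic cohort is generated from `cohort`
    genotypes_path: str | None = None
    features_path: str | None = None
    covariates_path: str | None = None
    trait_path: str | None = None
    cohort: dict = field(default_factory=dict)
    # embedding stage
    n_components: int = 40
    rank_normalize: bool = True
    # contrastive stage (optional; slow)
    train_encoder: bool = False
    encoder: dict = field(default_factory=dict)
    # association stage
    assoc_mode: str = "score"
    maf_min: float = 0.01
    run_univariate: bool = True
    n_perm: int = 0
    # clumping stage
    p_threshold: float = 5e-8
    r2_threshold: float = 0.1
    window_bp: int = 5_000_000
    window_convention: str = "span"
    # axis stage
    axis_q: float = 0.05
    axis_alphas: tuple = (0.0, 0.25, 0.5, 0.75, 1.0)

    def validate(self) -> None:
        if self.assoc_mode not in ("score", "refined"):
            raise ValueError("assoc_mode must be 'score' or 'refined'")
        if self.window_convention not in ("span", "index"):
            raise ValueError("window_convention must be 'span' or 'index'")
        if not (0 < self.axis_q < 0.5):
            raise ValueError("axis_q must be in (0, 0.5)")
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        SyntheticConfig(**{**self.cohort, "seed": self.seed}).validate()


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in raw:
        raise ValueError("config must set an explicit seed")
    if "axis_alphas" in raw:
        raw["axis_alphas"] = tuple(raw["axis_alphas"])
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    data = asdict(cfg)
    data["axis_alphas"] = list(data["axis_alphas"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
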