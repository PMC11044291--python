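"""Run configuration: one declarative YAML file, validated with pydantic.

All randomness flows from the single integer ``seed``; each pipeline stage
derives a named substream (see :func:`substream`) so stages are independently
reproducible.
"""

from __future__ import annotations

import zlib
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .types import ConfigurationError

#: The extended MHC interval as printed in the source GWAS convention
#: (chromosome 6, 1-based closed); excluded for its long-range complex LD.
DEFAULT_MHC_REGION = ("6", 28477797, 33448354)

DEFAULT_BRAIN_KEYWORDS = [
    "brain",
    "cortex",
    "dlpfc",
    "cerebellum",
    "hippocampus",
    "frontal",
    "psychencode",
    "cmc",
]


class LayerConfig(BaseModel):
    """Simulation settings for one molecular layer."""

    n_features: int = Field(gt=0)
    n_causal: int = Field(default=1, gt=0)
    effect_sd: float = Field(default=0.6, ge=0)
    residual_sd: float = Field(default=1.0, ge=0)
    sharing_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    tissue_label: str = "brain_cortex"
    dataset_tag: str = "SIMPANEL"


class TraitConfig(BaseModel):
    """How the simulated disorder trait loads on the molecular layers."""

    mediated_fraction: float = Field(default=0.20, ge=0.0, le=1.0)
    bxy_sd: float = Field(default=0.3, ge=0)
    n_direct: int = Field(default=10, ge=0)
    direct_sd: float = Field(default=0.15, ge=0)
    residual_sd: float = Field(default=1.0, gt=0)


class SimulationConfig(BaseModel):
    """Cohort-level settings for the synthetic genotype/molecular/trait generator."""

    n_individuals: int = Field(default=2000, gt=1)
    n_variants: int = Field(default=1200, gt=0)
    block_size: int = Field(default=20, gt=0)
    within_block_r: float = Field(default=0.6, ge=0.0, lt=1.0)
    maf_range: tuple[float, float] = (0.05, 0.5)
    variant_spacing_bp: int = Field(default=10_000, gt=0)
    cis_window_bp: int = Field(default=500_000, gt=0)
    layers: dict[str, LayerConfig] = Field(
        default_factory=lambda: {
            "eQTL": LayerConfig(n_features=60, tissue_label="brain_cortex"),
            "sQTL": LayerConfig(
                n_features=30, sharing_fraction=0.4, tissue_label="brain_dlpfc"
            ),
            "pQTL": LayerConfig(
                n_features=20, sharing_fraction=0.4, tissue_label="brain_rosmap"
            ),
            "mQTL": LayerConfig(
                n_features=30, sharing_fraction=0.4, tissue_label="blood"
            ),
            "m6AQTL": LayerConfig(
                n_features=15, sharing_fraction=0.4, tissue_label="brain_m6a"
            ),
        }
    )
    trait: TraitConfig = Field(default_factory=TraitConfig)
    disorders: list[str] = Field(default_factory=lambda: ["SCZ", "BP"])
    old_gwas_fraction: float = Field(default=0.6, gt=0.0, le=1.0)

    @field_validator("maf_range")
    @classmethod
    def _check_maf(cls, v: tuple[float, float]) -> tuple[float, float]:
        lo, hi = v
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        return v


class AnalysisConfig(BaseModel):
    """Thresholds and constants governing every analysis stage."""

    seed: int = 0
    mhc_region: tuple[str, int, int] = DEFAULT_MHC_REGION
    bonferroni_alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    heidi_retain_threshold: float = Field(default=0.05, gt=0.0, lt=1.0)
    novelty_threshold: float = Field(default=5e-8, gt=0.0, lt=1.0)
    reliable_min_count: int = Field(default=2, ge=1)
    window_bp: int = Field(default=1_000_000, gt=0)
    instrument_p_threshold: float = Field(default=5e-8, gt=0.0, lt=1.0)
    brain_keywords: list[str] = Field(
        default_factory=lambda: list(DEFAULT_BRAIN_KEYWORDS)
    )
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)

    @model_validator(mode="after")
    def _check_region(self) -> "AnalysisConfig":
        _, start, end = self.mhc_region
        if start > end:
            raise ValueError("mhc_region start > end")
        return self


def load_config(path: str | Path) -> AnalysisConfig:
    """Read a YAML config file; unknown keys are rejected by pydantic."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    try:
        return AnalysisConfig(**payload)
    except Exception as exc:  # pydantic ValidationError
        raise ConfigurationError(str(exc)) from exc


def substream(seed: int, name: str) -> np.random.Generator:
    """Derive a named, reproducible RNG substream from the master seed.

    The name is hashed with crc32 so adding a new stage never perturbs the
    streams of existing stages.
    """
    child = (int(seed) ^ zlib.crc32(name.encode())) % (2**31 - 1)
    return np.random.default_rng(child)
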