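"""Pipeline-wide scalar configuration.

All thresholds of the analysis live in one validated dataclass so every stage
reads the same numbers: DE calling (|log2FC| > 2, adjusted p < 0.05, delta > 2
for replicate-free comparisons), core construction (>= 10 bp three-way
overlap), promoter geometry (2 kb upstream of the TSS), motif work (+/- 50 bp
flanks, relative log-odds score >= 0.8, pseudocount 1), orthology acceptance
(confidence 1 or >= 30 % homology) and cohort stratification (quartile or
decile fraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    lfc_threshold: float = 2.0          # |log2 fold-change| must exceed this
    padj_threshold: float = 0.05        # adjusted p must be below this
    delta_threshold: float = 2.0        # log2 units, replicate-free delta DE
    min_overlap_bp: int = 10            # n-way peak overlap for core regions
    promoter_length_bp: int = 2000      # upstream of canonical TSS
    flank_bp: int = 50                  # co-motif window half-width
    pwm_relative_score_min: float = 0.8  # fraction of the max log-odds score
    pwm_pseudocount: float = 1.0
    rng_seed: int = 0
    quantile_fraction: float = 0.25     # 0.25 = quartiles, 0.10 = deciles
    orthology_min_confidence: int = 1
    orthology_min_homology_pct: float = 30.0
    chrom_rename: dict = field(default_factory=dict)  # strict-match rename map
    biotype_coding: tuple = ("protein_coding",)       # GTF biotypes -> coding

    def __post_init__(self) -> None:
        for name in ("lfc_threshold", "padj_threshold", "delta_threshold",
                     "min_overlap_bp", "promoter_length_bp", "flank_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 < self.quantile_fraction <= 0.5:
            raise ValueError("quantile_fraction must be in (0, 0.5]")
        if not 0.0 < self.pwm_relative_score_min <= 1.0:
            raise ValueError("pwm_relative_score_min must be in (0, 1]")
        if self.pwm_pseudocount < 0:
            raise ValueError("pwm_pseudocount must be non-negative")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML mapping of PipelineConfig fields; absent fields default."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = PipelineConfig.__dataclass_fields__
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "biotype_coding" in data:
        data["biotype_coding"] = tuple(data["biotype_coding"])
    return PipelineConfig(**data)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    data = asdict(cfg)
    data["biotype_coding"] = list(data["biotype_coding"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
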