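"""Structured run configuration with strict key validation.

Defaults follow the published analysis settings: MAF < 1% and call rate
< 90% removal, 0.95/0.05 G blending, 1.5-Mb windows, 15-kb gene flanks,
top 1% of SNP effects, Bonferroni alpha 0.01.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .synthetic import SimConfig


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    seed: int = 0
    # QC
    maf_min: float = 0.01
    callrate_min: float = 0.90
    autosomes_only: bool = True
    # G / H
    blend_weight: float = 0.95
    # additive scan
    window_bp: int = 1_500_000
    sliding_windows: bool = True
    sigma_u2: float | None = None
    sigma_pe2: float | None = None
    sigma_e2: float | None = None
    covariates: list = field(default_factory=list)
    # non-additive scan
    codings: list = field(default_factory=lambda: ["dominance", "recessive", "overdominance"])
    bonferroni_alpha: float = 0.01
    genomic_control: bool = True
    # gene-set stage
    flank_bp: int = 15_000
    top_fraction: float = 0.01
    enrichment_alpha: float = 0.05
    # simulation block
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if not 0 <= self.maf_min < 0.5:
            raise ConfigError("maf_min must be in [0, 0.5)")
        if not 0 <= self.callrate_min <= 1:
            raise ConfigError("callrate_min must be in [0, 1]")
        if not 0 < self.blend_weight <= 1:
            raise ConfigError("blend_weight must be in (0, 1]")
        if self.window_bp < 1 or self.flank_bp < 0:
            raise ConfigError("window_bp must be >= 1 and flank_bp >= 0")
        if not 0 < self.top_fraction <= 1:
            raise ConfigError("top_fraction must be in (0, 1]")
        for a in (self.bonferroni_alpha, self.enrichment_alpha):
            if not 0 < a < 1:
                raise ConfigError("significance levels must be in (0, 1)")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        sim = data.pop("sim", None)
        if sim is not None:
            sim_known = {f.name for f in dataclasses.fields(SimConfig)}
            sim_unknown = set(sim) - sim_known
            if sim_unknown:
                raise ConfigError(f"unknown sim keys: {sorted(sim_unknown)}")
            for key in ("founder_maf_range", "records_per_animal_range", "reliability_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            data["sim"] = SimConfig(**sim)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
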