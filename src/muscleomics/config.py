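"""Pipeline configuration: YAML-backed, validated, defaults = published values."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = [
    "ProteomicsConfig",
    "EnrichmentConfig",
    "MetabolomicsConfig",
    "IOConfig",
    "PipelineConfig",
    "load_config",
    "save_config",
]


class ConfigError(ValueError):
    pass


@dataclass
class ProteomicsConfig:
    f: float = 0.5
    rsc_threshold: float = 1.40
    min_peptides: int = 2
    min_score: float = 19.0
    group_a: str = "VPG"  # focus group: positive Rsc = higher here
    group_b: str = "CG"

    def validate(self) -> None:
        if self.f <= 0 or self.rsc_threshold <= 0:
            raise ConfigError("proteomics: f and rsc_threshold must be > 0")
        if self.min_peptides < 0 or self.min_score < 0:
            raise ConfigError("proteomics: filter thresholds must be >= 0")
        if self.group_a == self.group_b:
            raise ConfigError("proteomics: group labels must differ")


@dataclass
class EnrichmentConfig:
    mode: str = "fdr"  # gate on p or on fdr
    alpha_p: float = 0.05
    alpha_fdr: float = 0.05
    min_background_members: int = 2
    ease: bool = False

    def validate(self) -> None:
        if self.mode not in ("p", "fdr"):
            raise ConfigError("enrichment: mode must be 'p' or 'fdr'")
        if not (0 < self.alpha_p <= 1 and 0 < self.alpha_fdr <= 1):
            raise ConfigError("enrichment: alphas must lie in (0, 1]")


@dataclass
class MetabolomicsConfig:
    n_components: int = 2
    vip_cutoff: float = 1.5
    alpha: float = 0.05
    alpha_normality: float = 0.05
    linkage: str = "ward"
    volcano_fc_threshold_log2: float = 0.0
    heatmap_top_k: int = 40

    def validate(self) -> None:
        if self.n_components < 1:
            raise ConfigError("metabolomics: n_components must be >= 1")
        if self.vip_cutoff < 0:
            raise ConfigError("metabolomics: vip_cutoff must be >= 0")
        if not (0 < self.alpha <= 1 and 0 < self.alpha_normality <= 1):
            raise ConfigError("metabolomics: alphas must lie in (0, 1]")
        if self.linkage not in ("ward", "single", "complete", "average"):
            raise ConfigError(f"metabolomics: unknown linkage {self.linkage!r}")


@dataclass
class IOConfig:
    identifications: str | None = None
    rsc_table: str | None = None  # precomputed per-protein Rsc (accession, gene, rsc)
    metabolite_panel: str | None = None
    metabolite_groups: str | None = None
    gmt: str | None = None
    out_dir: str = "results"


@dataclass
class PipelineConfig:
    proteomics: ProteomicsConfig = field(default_factory=ProteomicsConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    metabolomics: MetabolomicsConfig = field(default_factory=MetabolomicsConfig)
    io: IOConfig = field(default_factory=IOConfig)
    seed: int = 0

    def validate(self) -> None:
        self.proteomics.validate()
        self.enrichment.validate()
        self.metabolomics.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Short stable hash identifying the exact configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _build(cls, data: dict, path: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {path}: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML config; missing keys get defaults, unknown keys are errors."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    allowed = {"proteomics", "enrichment", "metabolomics", "io", "seed"}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    cfg = PipelineConfig(
        proteomics=_build(ProteomicsConfig, raw.get("proteomics", {}) or {}, "proteomics"),
        enrichment=_build(EnrichmentConfig, raw.get("enrichment", {}) or {}, "enrichment"),
        metabolomics=_build(MetabolomicsConfig, raw.get("metabolomics", {}) or {}, "metabolomics"),
        io=_build(IOConfig, raw.get("io", {}) or {}, "io"),
        seed=int(raw.get("seed", 0)),
    )
    cfg.validate()
    return cfg


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
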