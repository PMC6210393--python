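"""Validated pipeline configuration (YAML-backed, schema-checked).

A pipeline run is described by one document with a block per stage; unknown
keys are rejected and cross-parameter constraints (b <= t, 0 < d < 1, ...)
are enforced at load time.  Every run echoes its fully-populated effective
config to the output directory so results can be reproduced bit-identically.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .errors import ConfigError
from .gan import GanConfig
from .pagerank import PageRankConfig
from .prognosis import EvalConfig
from .synthetic import SimConfig

SCHEMA_VERSION = 1


class DataPaths(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mrna: Optional[str] = None
    cnv: Optional[str] = None
    methylation: Optional[str] = None
    snp: Optional[str] = None
    network: str
    clinical: str

    @model_validator(mode="after")
    def _check(self) -> "DataPaths":
        if not any([self.mrna, self.cnv, self.methylation, self.snp]):
            raise ValueError("at least one omics layer path is required")
        return self

    def layer_paths(self) -> dict[str, str]:
        pairs = {
            "mRNA": self.mrna,
            "CNV": self.cnv,
            "methylation": self.methylation,
            "SNP": self.snp,
        }
        return {tag: p for tag, p in pairs.items() if p}

    def check_exists(self) -> None:
        paths = list(self.layer_paths().values()) + [self.network, self.clinical]
        missing = [p for p in paths if not Path(p).is_file()]
        if missing:
            raise ConfigError(f"input files not found: {missing}")


class NetworkConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    top_n: int = 400  # per-layer |t| cutoff N
    normalize_axis: str = "sample"
    zscore_ddof: int = 0
    missing_policy: str = "drop"

    @model_validator(mode="after")
    def _check(self) -> "NetworkConfig":
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.normalize_axis not in ("gene", "sample"):
            raise ValueError("normalize_axis must be 'gene' or 'sample'")
        if self.missing_policy not in ("drop", "mean"):
            raise ValueError("missing_policy must be 'drop' or 'mean'")
        return self


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    schema_version: int = SCHEMA_VERSION
    sim: Optional[SimConfig] = None
    data: Optional[DataPaths] = None
    network: NetworkConfig = NetworkConfig()
    gan: GanConfig = GanConfig()
    rank: PageRankConfig = PageRankConfig()
    predict: EvalConfig = EvalConfig()
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if self.sim is None and self.data is None:
            raise ValueError("config needs a 'sim' block or a 'data' block")
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {self.schema_version}")
        return self


def validate_config(path) -> PipelineConfig:
    """Load and schema-validate a YAML pipeline config file."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config document must be a mapping")
    try:
        cfg = PipelineConfig(**raw)
    except ValidationError as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc
    if cfg.data is not None:
        cfg.data.check_exists()
    return cfg


def echo_config(cfg: PipelineConfig, outdir) -> Path:
    """Write the effective config (defaults applied) for provenance."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "config_used.yaml"
    path.write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
    return path
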