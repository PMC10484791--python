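"""Analysis configuration: every threshold used across the pipeline.

Defaults are the study conditions; any of them can be overridden from a YAML
file. Unknown keys and type mismatches are rejected loudly so that a typo in
a config never silently reverts to a default.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = ["AnalysisConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a config file fails schema validation."""


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    # bulk screen scoring
    prior_count: float = Field(0.5, gt=0)
    logratio_trim: float = Field(0.30, gt=0, lt=0.5)
    sum_trim: float = Field(0.05, gt=0, lt=0.5)
    tmm_weighting: bool = True
    background_ntc_only: bool = False
    alpha: float = Field(0.05, gt=0, le=1)
    gene_hit_pct: float = Field(50.0, gt=0, le=100)
    # single-cell QC
    min_genes: int = Field(500, gt=0)
    min_umis: int = Field(1000, gt=0)
    pct_of_p90: float = Field(0.20, gt=0, le=1)
    max_mito: float = Field(0.10, gt=0, le=1)
    # guide assignment
    guide_fraction: float = Field(0.75, gt=0, le=1)
    # cell-type relabeling and enrichment
    relabel_min_fraction: float = Field(0.10, gt=0, le=1)
    min_ntc_cells: int = Field(5, gt=0)
    min_ntc_fraction: float = Field(0.25, gt=0, le=1)
    # viability
    viability_pseudo: float = Field(0.5, gt=0)
    # trajectory
    k_diffusion: int = Field(30, gt=0)
    n_dcs: int = Field(10, gt=0)
    k_transfer: int = Field(15, gt=0)
    n_pcs_transfer: int = Field(8, gt=0)
    k_project: int = Field(20, gt=0)
    # peak rules
    lfc_min: float = Field(0.75, gt=0)
    padj_max: float = Field(0.01, gt=0, le=1)
    min_cpm: float = Field(2.0, ge=0)
    min_reads: int = Field(10, ge=0)
    gained_min: float = 1.0
    lost_max: float = -1.0
    shared_abs_max: float = Field(0.5, gt=0)
    # reproducibility
    seed: int = Field(0, ge=0)

    def digest(self) -> str:
        """Stable hash of the effective configuration."""
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load a YAML config; absent keys fall back to defaults, unknown keys
    and type mismatches raise :class:`ConfigError` naming the offender."""
    if path is None:
        return AnalysisConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return AnalysisConfig(**raw)
    except ValidationError as err:
        details = "; ".join(
            f"{'.'.join(str(x) for x in e['loc']) or '<root>'}: {e['msg']}"
            for e in err.errors()
        )
        raise ConfigError(f"invalid config {path}: {details}") from err
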