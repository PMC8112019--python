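"""Run configuration: a schema-validated YAML surface over the pipeline.

Unknown keys are rejected (pydantic ``extra="forbid"``); a serialised copy of
the validated config is written into every output manifest.  Defaults mirror
the reference analysis settings: 116 regions, strict >10% dropout exclusion,
4:1:1 subject-grouped splits, and the 256-filter / 1x58 / 3x64 / 0.5-dropout
/ 100-epoch network.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["RunConfig", "load_config"]


class _Forbid(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PathsBlock(_Forbid):
    atlas: str | None = None
    grey_matter_dir: str | None = None
    timeseries_dir: str | None = None
    covariates: str | None = None
    output_dir: str = "wassconn_out"


class MatchBlock(_Forbid):
    caliper_age: float = Field(3.0, gt=0)
    caliper_fwd: float = Field(0.1, gt=0)
    caliper_icv: float = Field(0.5, gt=0)


class ModelBlock(_Forbid):
    n_filters: int = Field(256, ge=1)
    dense_units: int = Field(64, ge=1)
    n_dense: int = Field(3, ge=1)
    dropout: float = Field(0.5, ge=0, lt=1)
    epochs: int = Field(100, ge=1)
    batch_size: int = Field(64, ge=2)
    learning_rate: float = Field(1e-3, gt=0)
    n_models: int = Field(10, ge=1)
    channels: list[str] = ["structural"]
    redraw_permutation: bool = True


class SaliencyBlock(_Forbid):
    target_class: str = "case"  # or "predicted"
    top_k_hubs: int = Field(3, ge=1)
    length_rule: str = "reciprocal"  # or "max_minus"


class SyntheticBlock(_Forbid):
    n_regions: int = 16
    n_cases: int = 200
    n_controls: int = 200
    planted_regions: list[int] = [1, 2]
    struct_effect: float = 1.5
    func_effect: float = 0.0
    n_timepoints: int = 120
    match_yield_floor: float = Field(0.5, ge=0, le=1)


class RunConfig(_Forbid):
    """Top-level validated run configuration."""

    paths: PathsBlock = PathsBlock()
    match: MatchBlock = MatchBlock()
    model: ModelBlock = ModelBlock()
    saliency: SaliencyBlock = SaliencyBlock()
    synthetic: SyntheticBlock = SyntheticBlock()
    dropout_threshold: float = Field(0.10, gt=0, lt=1)
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)
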