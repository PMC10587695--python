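"""Validated run configuration for the end-to-end pipeline.

A :class:`RunConfig` is the single YAML-serializable document that drives
``polstain pipeline``: one global seed fans out to per-stage seeds (stable
hash of the stage name) so stages can be re-run independently yet
deterministically.
"""

from __future__ import annotations

import zlib
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = ["RunConfig", "PhantomStage", "TrainStage", "EvaluateStage", "stage_seed", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a run configuration fails schema validation."""


class PhantomStage(BaseModel):
    n_scenes: int = Field(10, ge=2)
    train_fraction: float = Field(0.8, gt=0.0, lt=1.0)
    palette: str = "HE"
    sop: str = "LIN45"
    paired: bool = True
    size: int = Field(64, ge=64)
    n_nuclei: int = Field(12, ge=0)
    n_fibers: int = Field(4, ge=0)
    magnifications: tuple[float, ...] = (1.0, 2.0)


class TrainStage(BaseModel):
    epochs: int = Field(2, ge=1)
    flat_epochs: int = Field(1, ge=0)
    batch_size: int = Field(2, ge=1)
    lr0: float = Field(2e-4, gt=0)
    lambda_cyc: float = Field(10.0, ge=0)
    gan_mode: str = "log"
    base_width: int = Field(8, ge=4)
    disc_widths: tuple[int, ...] = (8, 16, 32, 64, 1)
    n_res_blocks: int = Field(9, ge=1)

    @field_validator("gan_mode")
    @classmethod
    def _mode(cls, v):
        if v not in ("log", "least_squares"):
            raise ValueError(f"gan_mode must be log or least_squares, got {v!r}")
        return v


class EvaluateStage(BaseModel):
    mode: str = "paired"  # paired | cycle

    @field_validator("mode")
    @classmethod
    def _mode(cls, v):
        if v not in ("paired", "cycle"):
            raise ValueError(f"mode must be paired or cycle, got {v!r}")
        return v


class RunConfig(BaseModel):
    seed: int = 0
    out_root: str = "runs/run0"
    log_level: str = "INFO"
    phantom: PhantomStage = Field(default_factory=PhantomStage)
    train: TrainStage = Field(default_factory=TrainStage)
    evaluate: EvaluateStage = Field(default_factory=EvaluateStage)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
            return cls(**raw)
        except Exception as e:  # surface the offending field path
            raise ConfigError(str(e)) from None

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: global seed mixed with a stable hash
    of the stage name (crc32, platform-independent)."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)
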