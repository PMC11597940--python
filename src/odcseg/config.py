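"""YAML run configuration: validation, defaults, deterministic hashing.

Unknown keys are rejected so a typo in a config file fails loudly; every
default matches the shipped training recipe (CLAHE clip 2.0 on an (8, 8)
tile grid, 200 px ROI margin, loss space weights 0.2/0.8, Adam learning
rates 1e-4/1e-2, StepLR gamma 0.95).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, model_validator


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SynthSection(_Section):
    image_size: int = 256
    n_normal: int = 20
    n_glaucoma: int = 12
    n_val_normal: int = 0
    n_val_glaucoma: int = 12
    cdr_range_normal: tuple[float, float] = (0.3, 0.5)
    cdr_range_glaucoma: tuple[float, float] = (0.6, 0.85)
    glaucoma_annotated_fraction: float = 0.5

    @model_validator(mode="after")
    def _check_ranges(self):
        for lo, hi in (self.cdr_range_normal, self.cdr_range_glaucoma):
            if not (0.0 < lo < hi < 1.0):
                raise ValueError("CDR ranges must satisfy 0 < lo < hi < 1")
        return self


class PreprocessSection(_Section):
    margin: int = 200
    clip_limit: float = 2.0
    tile_grid: tuple[int, int] = (8, 8)
    per_channel: bool = False
    size: int = 256

    @model_validator(mode="after")
    def _check(self):
        if self.margin < 0:
            raise ValueError("preprocess.margin must be nonnegative")
        return self


class ModelSection(_Section):
    base_width: int = 64
    upsample_encoding: bool = False

    @model_validator(mode="after")
    def _check(self):
        if self.base_width % 4 != 0:
            raise ValueError("model.base_width must be divisible by 4")
        return self


class LossSection(_Section):
    w_e: float = 0.2
    w_o: float = 0.8
    phase1_w_seg: float = 1.0
    phase1_w_style: float = 0.05
    phase2_w_domain: float = 1.0

    @model_validator(mode="after")
    def _check(self):
        if abs(self.w_e + self.w_o - 1.0) > 1e-9:
            raise ValueError("loss.w_e and loss.w_o must sum to 1")
        return self


class TrainSection(_Section):
    scenario: int = 1
    epochs: int = 30
    phase1_fraction: float = 0.8
    batch_size: int = 2
    lr_seg: float = 1e-4
    lr_disc: float = 1e-2
    betas: tuple[float, float] = (0.9, 0.99)
    lr_gamma: float = 0.95
    keep_seg_in_phase2: bool = True

    @model_validator(mode="after")
    def _check(self):
        if self.scenario not in (1, 2, 3):
            raise ValueError("train.scenario must be 1, 2 or 3")
        if not (0.0 < self.phase1_fraction <= 1.0):
            raise ValueError("train.phase1_fraction must be in (0, 1]")
        return self


class GscoreSection(_Section):
    region: str = "mean_od_oc_iou"
    direction: str = "vertical"


class RunConfig(_Section):
    synth: SynthSection = SynthSection()
    preprocess: PreprocessSection = PreprocessSection()
    model: ModelSection = ModelSection()
    loss: LossSection = LossSection()
    train: TrainSection = TrainSection()
    gscore: GscoreSection = GscoreSection()

    def to_canonical_dict(self) -> dict:
        return json.loads(self.model_dump_json())

    def config_hash(self) -> str:
        payload = json.dumps(self.to_canonical_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_canonical_dict(), sort_keys=True)


class ConfigError(ValueError):
    pass


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; an empty file yields all defaults."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return RunConfig(**raw)
    except Exception as exc:  # pydantic ValidationError carries the key names
        raise ConfigError(str(exc)) from exc


def loads_config(text: str) -> RunConfig:
    raw = yaml.safe_load(text) or {}
    try:
        return RunConfig(**raw)
    except Exception as exc:
        raise ConfigError(str(exc)) from exc
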