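"""Run configuration: one validated YAML file drives the whole pipeline.

Every field has a default mirroring the method's stated parameters
(selector population 50, DE F=0.2 / Cr=0.7, 10-fold evaluation, PCA k=1000);
unknown keys are rejected with the offending key path.  A single global seed
deterministically derives per-stage seeds (stage-name hashing) so each stage
is independently replayable.
"""

from __future__ import annotations

import zlib
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .classify_eval import CLASSIFIER_NAMES


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SyntheticInput(_Strict):
    n_per_class: int = 50
    n_classes: int = 4
    d: int = 60
    n_informative: int = 8
    n_redundant: int = 8
    class_sep: float = 4.0
    noise_sd: float = 1.0


class InputConfig(_Strict):
    features: Optional[str] = None
    images: Optional[str] = None
    layout: Literal["per-class-folders", "nifti-volumes"] = "per-class-folders"
    classes: Optional[list[str]] = None
    blank_threshold: float = 0.0
    synthetic: Optional[SyntheticInput] = None


class TrainSection(_Strict):
    epochs: int = Field(10, ge=1)
    learning_rate: float = 1e-4
    batch_size: int = Field(32, ge=1)
    momentum: float = Field(0.0, ge=0.0, lt=1.0)


class BackboneSection(_Strict):
    architecture: str = "resnet101"
    feature_layer: str = "pool5"
    num_classes: int = Field(4, ge=2)
    pretrained: bool = False
    weights_path: Optional[str] = None
    normalization: Literal["unit", "imagenet", "none"] = "unit"
    finetune: bool = False
    train: TrainSection = TrainSection()


class DESection(_Strict):
    population: int = Field(50, ge=4)
    scale_factor: float = 0.2
    crossover_rate: float = Field(0.7, ge=0.0, le=1.0)
    max_generations: int = Field(50, ge=0)
    decode_threshold: float = 0.5


class PSOSection(_Strict):
    population: int = Field(50, ge=2)
    inertia: float = 0.7
    cognitive: float = 2.0
    social: float = 2.0
    max_generations: int = Field(50, ge=0)
    velocity_clamp: Optional[float] = None
    decode_threshold: float = 0.5


class FitnessSection(_Strict):
    neighbors: int = Field(1, ge=1)
    eval_scheme: Literal["holdout", "kfold"] = "holdout"
    holdout_fraction: float = Field(0.3, gt=0.0, lt=1.0)
    repeats: int = Field(3, ge=1)
    folds: int = Field(5, ge=2)


class PCASection(_Strict):
    k: int = Field(1000, ge=1)


class EvaluateSection(_Strict):
    folds: int = Field(10, ge=2)
    classifiers: list[str] = Field(default_factory=lambda: list(CLASSIFIER_NAMES))

    def model_post_init(self, __context) -> None:
        bad = [c for c in self.classifiers if c not in CLASSIFIER_NAMES]
        if bad:
            raise ValueError(f"unknown classifiers {bad}; "
                             f"choose from {CLASSIFIER_NAMES}")


class RunConfig(_Strict):
    seed: int = 0
    outdir: Optional[str] = None
    input: InputConfig = InputConfig()
    backbone: BackboneSection = BackboneSection()
    de: DESection = DESection()
    pso: PSOSection = PSOSection()
    fitness: FitnessSection = FitnessSection()
    pca: PCASection = PCASection()
    evaluate: EvaluateSection = EvaluateSection()

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed: global seed mixed with a stage-name hash."""
        return (self.seed ^ zlib.crc32(stage.encode())) % (2 ** 31)

    def snapshot(self) -> dict:
        return self.model_dump()


class ConfigError(ValueError):
    pass


def parse_config(path: str | Path | None = None,
                 overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML run config; ``None``/empty file → all defaults.

    Errors name the offending key path.  ``overrides`` (nested dict) are
    applied on top of the file before validation, so CLI flags win.
    """
    data: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file {p} does not exist")
        loaded = yaml.safe_load(p.read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{p}: top level must be a mapping")
        data = loaded
    for key, value in (overrides or {}).items():
        node = data
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        locs = "; ".join(
            ".".join(str(x) for x in err["loc"]) + ": " + err["msg"]
            for err in exc.errors())
        raise ConfigError(f"invalid config: {locs}") from exc
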