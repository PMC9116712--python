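"""Structured run configuration (YAML + dotted-path overrides).

Unknown keys are rejected everywhere; a run's fully resolved config is
serialized next to its artifacts so any result can be traced to the exact
settings that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeneratorConfig(_Section):
    n_pos: int = 40
    n_neg: int = 360
    specked: float = 0.15
    understained: float = 0.15
    multicell: float = 0.10
    image_size: int = 224
    seed: int = 0

    @property
    def confounder_rates(self) -> dict:
        return {"specked": self.specked, "understained": self.understained,
                "multicell": self.multicell}


class PipelineConfig(_Section):
    variant: str = "TVAD"
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    neg_train_target: int | None = None
    angle_range: tuple[float, float] = (-180.0, 180.0)
    scale_range: tuple[float, float] = (0.85, 1.15)
    seed: int = 0


class ModelConfig(_Section):
    pretrained: bool = False
    checkpoint: str | None = None
    init_seed: int = 0


class LossConfig(_Section):
    type: str = "focal"
    gamma: float = 2.0


class TrainingConfig(_Section):
    epochs: int = 60
    lr0: float = 0.01
    decay_factor: float = 0.1
    decay_every: int = 20
    batch_size: int = 32
    momentum: float = 0.9
    weight_decay: float = 5e-4
    clip_norm: float = 1.0
    seed: int = 0


class EvaluationConfig(_Section):
    threshold: float = 0.5


class PathsConfig(_Section):
    run_dir: str = "runs/latest"
    data_dir: str = "data"


class RunConfig(_Section):
    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    pipeline: PipelineConfig = Field(default_factory=PipelineConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)
    loss: LossConfig = Field(default_factory=LossConfig)
    training: TrainingConfig = Field(default_factory=TrainingConfig)
    evaluation: EvaluationConfig = Field(default_factory=EvaluationConfig)
    paths: PathsConfig = Field(default_factory=PathsConfig)

    def resolved_json(self) -> str:
        return json.dumps(self.model_dump(), indent=2, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.resolved_json().encode()).hexdigest()[:8]


def _set_dotted(data: dict, dotted: str, raw: str) -> None:
    keys = dotted.split(".")
    node = data
    for k in keys[:-1]:
        node = node.setdefault(k, {})
    node[keys[-1]] = yaml.safe_load(raw)


def load_config(path: str | None = None,
                overrides: list[str] | None = None) -> RunConfig:
    """Load YAML config and apply ``section.key=value`` overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    for item in overrides or []:
        if "=" not in item:
            raise ValueError(f"override {item!r} is not of the form key.path=value")
        dotted, raw = item.split("=", 1)
        _set_dotted(data, dotted, raw)
    return RunConfig.model_validate(data)


def write_resolved(cfg: RunConfig, run_dir: str | Path) -> Path:
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    out = run_dir / "resolved_config.json"
    out.write_text(cfg.resolved_json())
    return out
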