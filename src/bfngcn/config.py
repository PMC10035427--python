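"""Experiment configuration: a validated YAML schema.

Unknown keys are rejected before any computation starts, so a typo in a
config file fails fast instead of silently running defaults.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "SyntheticBlock", "BfnBlock", "FeaturesBlock", "TrainBlock",
    "EvaluationBlock", "ExperimentConfig", "load_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticBlock(_Strict):
    n_rois: int = 116
    n_timepoints: int = 135
    n_subjects_per_group: int = 40
    effect_rois: list[int] = Field(default_factory=list)  # fully-connected block
    effect_pairs: list[tuple[int, int]] = Field(default_factory=list)
    effect_delta: float = 0.0
    base_correlation: float = 0.2
    noise_sd: float = 0.25
    seed: int = 0


class BfnBlock(_Strict):
    estimator: Literal["pc", "sr", "lr"] = "pc"
    estimators: Optional[list[Literal["pc", "sr", "lr"]]] = None  # grid override
    lambda_: float = Field(default=0.1, alias="lambda", gt=0)
    binarize: bool = False
    threshold_keep_fraction: float = Field(default=0.3, gt=0, le=1)

    model_config = ConfigDict(extra="forbid", populate_by_name=True)


class FeaturesBlock(_Strict):
    sets: list[list[Literal["os", "oh", "ns", "cv"]]] = Field(
        default_factory=lambda: [["cv"]]
    )
    standardize: bool = True
    os_zscore: bool = False
    ns_keep_fraction: float = Field(default=0.3, gt=0, le=1)


class TrainBlock(_Strict):
    embedding_dim: int = 32
    epochs: int = 100
    learning_rate: float = 0.001
    weight_decay: float = 1e-3
    optimizer: str = "adam"
    batch_size: Optional[int] = None
    seed: int = 0


class EvaluationBlock(_Strict):
    n_repeats: int = 100
    train_fraction: float = 0.8
    seed: int = 0


class ExperimentConfig(_Strict):
    data_dir: Optional[str] = None
    synthetic: Optional[SyntheticBlock] = None
    bfn: BfnBlock = Field(default_factory=BfnBlock)
    features: FeaturesBlock = Field(default_factory=FeaturesBlock)
    train: TrainBlock = Field(default_factory=TrainBlock)
    evaluation: EvaluationBlock = Field(default_factory=EvaluationBlock)
    out_dir: str = "results"

    @model_validator(mode="after")
    def _one_source(self):
        if (self.data_dir is None) == (self.synthetic is None):
            raise ValueError("exactly one of data_dir / synthetic must be given")
        return self


def load_config(path) -> ExperimentConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return ExperimentConfig.model_validate(raw)
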