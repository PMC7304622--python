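"""Experiment configuration with lossless YAML round-tripping."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .groups import CONSECUTIVE_PAIRS


@dataclass
class GeneratorSettings:
    ages: list[int] = field(default_factory=lambda: list(range(1, 14)))
    n_per_age: int = 24
    canvas_size: int = 56
    split_fraction: float = 0.2
    separability: float = 1.0
    standardized_vertical_extent: int | None = None  # default 0.7 * canvas


@dataclass
class NetworkSettings:
    conv_channels: list[int] = field(default_factory=lambda: [8, 16])
    dense_units: int = 64


@dataclass
class TrainSettings:
    epochs: int = 20
    batch_size: int = 8
    learning_rate: float = 4e-4
    augment: bool = True


@dataclass
class LRPSettings:
    alpha: float = 1.0
    beta: float = 0.0
    stabilizer: float = 1e-9
    #: "predicted" propagates the model's predicted class; "read" the
    #: human read age
    target: str = "predicted"


@dataclass
class SpRAySettings:
    out_size: int = 56
    intermediate_size: int = 112
    perplexity: float = 30.0
    n_permutations: int = 199
    #: consecutive age-group pairs analyzed; binary maps are excluded
    #: from clustering (they vary only along the contour)
    pairs: list[list[str]] = field(
        default_factory=lambda: [list(p) for p in CONSECUTIVE_PAIRS])
    cluster_variants: list[str] = field(
        default_factory=lambda: ["baseline", "standardized"])
    #: group labels for F1: "predicted" (default) or "read"
    group_by: str = "predicted"


@dataclass
class ExperimentConfig:
    """Everything needed to regenerate an experiment bit-identically."""

    seed: int = 0
    variants: list[str] = field(
        default_factory=lambda: ["baseline", "binary", "standardized"])
    generator: GeneratorSettings = field(default_factory=GeneratorSettings)
    network: NetworkSettings = field(default_factory=NetworkSettings)
    train: TrainSettings = field(default_factory=TrainSettings)
    lrp: LRPSettings = field(default_factory=LRPSettings)
    spray: SpRAySettings = field(default_factory=SpRAySettings)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        sections = {
            "generator": GeneratorSettings,
            "network": NetworkSettings,
            "train": TrainSettings,
            "lrp": LRPSettings,
            "spray": SpRAySettings,
        }
        kwargs: dict = {}
        for key, typ in sections.items():
            if key in d:
                kwargs[key] = typ(**d.pop(key))
        kwargs.update(d)
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
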