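"""Model and training configuration.

``ModelConfig`` pins the encoder geometry (patch grid, embedding width, six
encoder layers by default) and selects dense vs. bi-level routed attention
and linear vs. KAN classification head. ``TrainConfig`` carries the
optimisation preset: learning rate 1e-4, 100 epochs, batch size 64, Adam —
the configuration that won the hyperparameter sweep — plus the regularisers
(dropout 0.5 on the head input, L2 weight decay, spline curvature penalty,
early stopping on validation loss).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = ["ModelConfig", "TrainConfig", "TEST_PRESET", "PAPER_SCALE_PRESET"]


@dataclass
class ModelConfig:
    image_size: int = 64
    patch_size: int = 8
    channels: int = 3
    embed_dim: int = 64
    num_layers: int = 6
    num_heads: int = 4
    mlp_ratio: int = 4
    drop_path_rate: float = 0.1
    dropout_rate: float = 0.5
    num_classes: int = 4
    attention_mode: str = "dense"  # "dense" | "routed"
    region_grid: int = 4  # S: regions per side of the patch grid
    routing_k: int = 4  # k: routed regions kept per region
    lce_kernel: int = 5  # depthwise-conv kernel of the local context term
    share_routing: bool = False  # share the routing index across heads
    head_type: str = "linear"  # "linear" | "kan"
    kan_num_basis: int = 5  # K: B-spline basis functions per edge
    kan_degree: int = 3
    kan_domain: float = 3.0  # knots span [-kan_domain, kan_domain]

    def __post_init__(self) -> None:
        if self.image_size % self.patch_size != 0:
            raise ValueError(
                f"patch_size {self.patch_size} must divide image_size {self.image_size}"
            )
        if self.embed_dim % self.num_heads != 0:
            raise ValueError(
                f"num_heads {self.num_heads} must divide embed_dim {self.embed_dim}"
            )
        if not 0.0 <= self.drop_path_rate <= 1.0:
            raise ValueError("drop_path_rate must lie in [0, 1]")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if self.attention_mode not in ("dense", "routed"):
            raise ValueError(f"unknown attention_mode {self.attention_mode!r}")
        if self.head_type not in ("linear", "kan"):
            raise ValueError(f"unknown head_type {self.head_type!r}")
        if self.attention_mode == "routed":
            g = self.grid_size
            if g % self.region_grid != 0:
                raise ValueError(
                    f"region_grid {self.region_grid} must divide the "
                    f"{g}x{g} patch-token grid"
                )
            if not 1 <= self.routing_k <= self.region_grid**2:
                raise ValueError(
                    f"routing_k must lie in [1, S^2={self.region_grid ** 2}]"
                )

    @property
    def grid_size(self) -> int:
        """Patch tokens per image side (H/p)."""
        return self.image_size // self.patch_size

    @property
    def num_patches(self) -> int:
        return self.grid_size**2

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.num_heads

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown ModelConfig keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "ModelConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 64
    optimizer: str = "adam"  # "adam" | "adagrad"
    weight_decay: float = 1e-4
    dropout: float = 0.5
    early_stopping_patience: int = 10
    kan_lambda: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("learning_rate, epochs and batch_size must be positive")
        if self.optimizer not in ("adam", "adagrad"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.weight_decay < 0 or self.kan_lambda < 0:
            raise ValueError("weight_decay and kan_lambda must be nonnegative")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "TrainConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown TrainConfig keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "TrainConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def TEST_PRESET(**overrides: Any) -> ModelConfig:
    """Desk-scale preset: 64x64 input, p=8 (8x8 token grid), d=64, h=4, L=6."""
    base: dict[str, Any] = dict(
        image_size=64, patch_size=8, embed_dim=64, num_heads=4, num_layers=6
    )
    base.update(overrides)
    return ModelConfig(**base)


def PAPER_SCALE_PRESET(**overrides: Any) -> ModelConfig:
    """Full-scale preset used only for profiling: 224x224, p=16, d=768, h=12.

    These hyperparameters are this package's choice of a standard ViT-Base
    geometry; the published parameter/FLOP counts are not reproduced by it.
    """
    base: dict[str, Any] = dict(
        image_size=224, patch_size=16, embed_dim=768, num_heads=12, num_layers=6,
        region_grid=7, routing_k=16,
    )
    base.update(overrides)
    return ModelConfig(**base)
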