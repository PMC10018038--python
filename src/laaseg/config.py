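"""Configuration dataclasses and YAML (de)serialization.

``NetworkConfig`` scales the architecture from the full-size network
(448x448 input, ConvNeXt-Tiny widths) down to desk-scale variants used in
tests; ``TrainConfig`` and ``LossWeights`` carry the published training
hyperparameters as defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


def _as_tuple(x):
    return tuple(x) if isinstance(x, (list, tuple)) else x


@dataclass
class NetworkConfig:
    """Architecture hyperparameters of the ConvNeXt U-shape networks.

    depths
        Number of ConvNeXt blocks per encoder stage (the published backbone
        uses the (3, 3, 9, 3) stage layout).
    dims
        Channel width per stage; defaults follow the ConvNeXt-Tiny
        convention (96, 192, 384, 768).
    """

    depths: tuple[int, int, int, int] = (3, 3, 9, 3)
    dims: tuple[int, int, int, int] = (96, 192, 384, 768)
    num_classes: int = 2
    input_size: tuple[int, int] = (448, 448)
    in_channels: int = 1

    def __post_init__(self):
        self.depths = _as_tuple(self.depths)
        self.dims = _as_tuple(self.dims)
        self.input_size = _as_tuple(self.input_size)
        self.validate()

    def validate(self) -> None:
        if len(self.depths) != 4 or len(self.dims) != 4:
            raise ValueError("depths and dims must both have 4 stages")
        if any(d <= 0 for d in self.dims) or any(d <= 0 for d in self.depths):
            raise ValueError("depths and dims must be positive")
        h, w = self.input_size
        if h % 32 or w % 32:
            raise ValueError(f"input_size must be divisible by 32, got {self.input_size}")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")

    @property
    def latent_channels(self) -> int:
        return self.dims[-1]

    def latent_spatial(self, input_size: tuple[int, int] | None = None) -> tuple[int, int]:
        h, w = input_size if input_size is not None else self.input_size
        return h // 32, w // 32


@dataclass
class LossWeights:
    """Weights and constants of the joint objective.

    All lambda weights default to 1 and the InfoNCE temperature tau to 0.1,
    matching the published setting; epsilon is the small positive constant
    in the soft-Dice denominator.
    """

    lambda_ce: float = 1.0
    lambda_dice: float = 1.0
    lambda_gan: float = 1.0
    lambda_cl: float = 1.0
    tau: float = 0.1
    epsilon: float = 1e-6
    num_classes: int = 2

    def __post_init__(self):
        if self.tau <= 0 or self.epsilon <= 0:
            raise ValueError("tau and epsilon must be positive")
        if min(self.lambda_ce, self.lambda_dice, self.lambda_gan, self.lambda_cl) < 0:
            raise ValueError("lambda weights must be non-negative")


@dataclass
class TrainConfig:
    """Optimization hyperparameters (published defaults, scalable sizes)."""

    lr_init: float = 1e-4
    beta1: float = 0.9
    batch_size: int = 8
    steps: int = 300
    recon_steps: int = 300
    input_size: tuple[int, int] = (448, 448)
    rot_range_deg: tuple[float, float] = (-10.0, 10.0)
    seed: int = 0
    lr_power: float = 0.9
    eval_interval: int = 50

    def __post_init__(self):
        self.input_size = _as_tuple(self.input_size)
        self.rot_range_deg = _as_tuple(self.rot_range_deg)
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (contrastive loss needs negatives)")
        lo, hi = self.rot_range_deg
        if abs(lo + hi) > 1e-9:
            raise ValueError("rotation range must be symmetric")


@dataclass
class SplitSpec:
    """Patient-level split with train:val:test image-count ratio."""

    ratio: tuple[float, float, float] = (4.0, 1.0, 1.0)
    patient_level: bool = True

    def __post_init__(self):
        self.ratio = _as_tuple(self.ratio)
        if len(self.ratio) != 3 or any(r <= 0 for r in self.ratio):
            raise ValueError("ratio must be 3 positive numbers")


@dataclass
class RunConfig:
    """Everything a full run needs, round-trippable through YAML."""

    network: NetworkConfig = field(default_factory=NetworkConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    losses: LossWeights = field(default_factory=LossWeights)
    data_dir: str = "."
    out_dir: str = "runs"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            network=NetworkConfig(**d.get("network", {})),
            train=TrainConfig(**d.get("train", {})),
            losses=LossWeights(**d.get("losses", {})),
            data_dir=d.get("data_dir", "."),
            out_dir=d.get("out_dir", "runs"),
            log_level=d.get("log_level", "INFO"),
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_listify(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d or {})


def _listify(obj):
    """YAML-friendly: tuples -> lists, recursively."""
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, list):
        return [_listify(v) for v in obj]
    return obj
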