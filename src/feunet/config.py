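"""Configuration dataclasses shared across the package, with YAML loading."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

RESNET34_BLOCKS = (3, 4, 6, 3)


class ConfigurationError(ValueError):
    """Raised when a configuration violates a structural constraint."""


@dataclass
class NetworkConfig:
    """Hyperparameters defining a full-encoder U-shaped segmentation network.

    ``N`` encoder levels at widths ``2**(i-1) * n``; the decoder mirrors those
    widths.  ``vgg16``-style backbones accept any depth in 2..6; the
    ``resnet34`` backbone is defined for N=5 with Basic-block counts ``w``.
    """

    backbone: str = "vgg16"
    N: int = 5
    n: int = 8
    n0: int = 3
    nc: int = 2
    k_e: int = 3
    w: tuple = RESNET34_BLOCKS

    def validate(self) -> "NetworkConfig":
        if self.backbone not in ("vgg16", "resnet34"):
            raise ConfigurationError(f"unknown backbone {self.backbone!r}; use 'vgg16' or 'resnet34'")
        if self.N < 2:
            raise ConfigurationError(f"encoder depth N must be >= 2, got {self.N}")
        if self.backbone == "vgg16" and self.N > 6:
            raise ConfigurationError(f"vgg16 backbone supports N in 2..6, got N={self.N}")
        if self.backbone == "resnet34":
            if self.N != 5:
                raise ConfigurationError(f"resnet34 backbone requires N=5, got N={self.N}")
            if tuple(self.w) != RESNET34_BLOCKS:
                raise ConfigurationError(f"resnet34 Basic-block counts must be {RESNET34_BLOCKS}, got {tuple(self.w)}")
        if self.n < 1:
            raise ConfigurationError(f"base channel count n must be >= 1, got {self.n}")
        if self.k_e % 2 == 0:
            raise ConfigurationError(f"kernel size k_e must be odd, got {self.k_e}")
        if self.n0 < 1 or self.nc < 2:
            raise ConfigurationError("need n0 >= 1 input channels and nc >= 2 classes")
        return self

    def encoder_channels(self) -> list[int]:
        """Output channels of encoder levels 1..N (level i has 2^(i-1)*n)."""
        return [self.n * 2 ** (i - 1) for i in range(1, self.N + 1)]


@dataclass
class LossSpec:
    """One or several loss components with their hyperparameters.

    ``alpha``/``beta`` weight false positives/negatives in the Tversky loss;
    ``lam``/``gamma`` are the focal-loss balance factor and exponent.
    """

    components: list = field(default_factory=lambda: ["CE"])
    weights: list | None = None
    alpha: float = 0.3
    beta: float = 0.7
    lam: float = 0.25
    gamma: float = 2.0
    include_background: bool = True

    def validate(self) -> "LossSpec":
        if self.weights is None:
            self.weights = [1.0] * len(self.components)
        if len(self.weights) != len(self.components):
            raise ConfigurationError("weights must match components in length")
        if self.alpha <= 0 or self.beta <= 0:
            raise ConfigurationError("Tversky alpha and beta must be positive")
        if self.gamma < 0:
            raise ConfigurationError("focal gamma must be >= 0")
        return self


@dataclass
class NoiseSpec:
    """Degradation recipe: Gaussian noise on images or impulse noise on labels."""

    kind: str = "gaussian_image"
    variance: float = 0.0
    seed: int = 0

    def validate(self) -> "NoiseSpec":
        if self.kind not in ("gaussian_image", "saltpepper_label"):
            raise ConfigurationError(f"unknown noise kind {self.kind!r}")
        if self.variance < 0:
            raise ConfigurationError("variance must be >= 0")
        if self.kind == "saltpepper_label" and self.variance > 1:
            raise ConfigurationError("salt-and-pepper fraction must be <= 1")
        return self


@dataclass
class SyntheticConfig:
    task: str = "liver_binary"
    n_samples: int = 16
    size: int = 64
    foreground_fraction_range: tuple = (0.08, 0.30)
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        lo, hi = self.foreground_fraction_range
        if not (0 < lo < hi < 1):
            raise ConfigurationError("foreground fraction range must satisfy 0 < lo < hi < 1")
        if self.task not in ("liver_binary", "brats_multiclass"):
            raise ConfigurationError(f"unknown task {self.task!r}")
        if self.n_samples < 1 or self.size < 8:
            raise ConfigurationError("need n_samples >= 1 and size >= 8")
        return self


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 2e-3
    batch_size: int = 5
    max_epochs: int = 500
    patience: int = 20
    lr_decay_factor: float = 0.1
    seed: int = 0
    loss: LossSpec = field(default_factory=LossSpec)
    monitor: str = "val_loss"  # or "val_dice"

    def validate(self) -> "TrainConfig":
        if min(self.learning_rate, self.weight_decay + 1e-30, self.batch_size, self.max_epochs) <= 0:
            raise ConfigurationError("learning_rate, batch_size and max_epochs must be positive")
        if self.patience < 1:
            raise ConfigurationError("patience must be >= 1")
        if not (0 < self.lr_decay_factor < 1):
            raise ConfigurationError("lr_decay_factor must lie in (0, 1)")
        self.loss.validate()
        return self


def load_yaml_config(path: str | Path) -> dict:
    """Read a YAML file holding any of the config sections used by the CLI."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    if "network" in raw:
        out["network"] = NetworkConfig(**raw["network"]).validate()
    if "loss" in raw:
        out["loss"] = LossSpec(**raw["loss"]).validate()
    if "train" in raw:
        tr = dict(raw["train"])
        if "loss" in tr:
            tr["loss"] = LossSpec(**tr["loss"])
        out["train"] = TrainConfig(**tr).validate()
    if "synthetic" in raw:
        sy = dict(raw["synthetic"])
        if "foreground_fraction_range" in sy:
            sy["foreground_fraction_range"] = tuple(sy["foreground_fraction_range"])
        out["synthetic"] = SyntheticConfig(**sy).validate()
    if "noise" in raw:
        out["noise"] = NoiseSpec(**raw["noise"]).validate()
    return out


def dump_config(cfg) -> dict:
    return asdict(cfg)
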