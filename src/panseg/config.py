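"""Run configuration and run logging.

A single YAML-serializable configuration drives every stage; the shipped
defaults are the published operating values (background threshold 200,
Reinhard on 5000-px crops with 50% overlap, 512-px tiles with stride 256,
50 epochs / batch 32 / lr 7e-4 / Adam, thresholds 0.3 / 0.5 / 0.7), so an
empty config reproduces the published settings.  The desk-scale preset
shrinks sizes only (64-px tiles, 128-px crops, small UNet) and leaves the
recipe untouched.

Every stochastic stage draws its seed from the run seed through a named
registry recorded in the run log, so identical config + seed reproduces
identical artifacts on one thread.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict

import yaml

from .fusion import ClassThresholds
from .models import TrainingConfig


@dataclass(frozen=True)
class NormalizationConfig:
    method: str = "reinhard"  # reinhard | macenko | vahadane
    mode: str = "crops"  # crops | whole
    crop_size: int = 5000
    overlap: float = 0.5
    background_threshold: int = 200
    space: str = "cielab"

    def validate(self):
        if self.method not in ("reinhard", "macenko", "vahadane"):
            raise ValueError(f"normalization.method: unknown method {self.method!r}")
        if self.mode not in ("crops", "whole"):
            raise ValueError(f"normalization.mode: unknown mode {self.mode!r}")
        if not (0 <= self.overlap < 1):
            raise ValueError("normalization.overlap: must lie in [0, 1)")
        if self.crop_size < 1:
            raise ValueError("normalization.crop_size: must be positive")


@dataclass(frozen=True)
class TilingConfig:
    tile_size: int = 512
    stride: int = 256

    def validate(self):
        if not (1 <= self.stride <= self.tile_size):
            raise ValueError("tiling.stride: must satisfy 1 <= stride <= tile_size")


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Synthetic-input settings used when the run generates its own data."""

    n_train: int = 10
    n_test: int = 5
    image_size: int = 256

    def validate(self):
        if self.n_train < 1 or self.n_test < 0:
            raise ValueError("synthetic.n_train/n_test: need >= 1 training image")


@dataclass(frozen=True)
class RunConfig:
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    tiling: TilingConfig = field(default_factory=TilingConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    thresholds: ClassThresholds = field(default_factory=ClassThresholds)
    synthetic: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)
    seed: int = 0

    def validate(self):
        self.normalization.validate()
        self.tiling.validate()
        self.synthetic.validate()
        # TrainingConfig / ClassThresholds validate in __post_init__

    # -- lossless round trip -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["training"]["augmentations"] = list(d["training"]["augmentations"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        try:
            tr = dict(d.get("training", {}))
            if "augmentations" in tr:
                tr["augmentations"] = tuple(tr["augmentations"])
            return cls(
                normalization=NormalizationConfig(**d.get("normalization", {})),
                tiling=TilingConfig(**d.get("tiling", {})),
                training=TrainingConfig(**tr),
                thresholds=ClassThresholds(**d.get("thresholds", {})),
                synthetic=SyntheticCohortConfig(**d.get("synthetic", {})),
                seed=int(d.get("seed", 0)),
            )
        except TypeError as e:
            raise ValueError(f"invalid configuration: {e}") from e

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        cfg = cls.from_dict(yaml.safe_load(text) or {})
        cfg.validate()
        return cfg

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def desk_run_config(seed: int = 0, **training_overrides) -> RunConfig:
    """Desk-scale preset: same recipe, small constants, minutes on one CPU."""
    return RunConfig(
        normalization=NormalizationConfig(crop_size=128),
        tiling=TilingConfig(tile_size=64, stride=32),
        training=TrainingConfig(
            model_scale=8, depth=2, input_size=64, seed=seed, **training_overrides
        ),
        seed=seed,
    )


class SeedRegistry:
    """Derives named child seeds from one run seed and records them."""

    def __init__(self, seed: int):
        self.root = int(seed)
        self.issued: dict[str, int] = {}

    def seed_for(self, name: str) -> int:
        h = hashlib.sha256(f"{self.root}:{name}".encode()).digest()
        s = int.from_bytes(h[:4], "big") % (2**31 - 1)
        self.issued[name] = s
        return s


class RunLog:
    """Timestamped stage records plus the seed registry, written as JSON."""

    def __init__(self, config: RunConfig):
        self.records = []
        self.config_hash = config.digest()
        self.t0 = time.time()

    def record(self, stage: str, **info):
        self.records.append(
            {"stage": stage, "elapsed_s": round(time.time() - self.t0, 3), **info}
        )

    def write(self, path, seeds: SeedRegistry):
        payload = {
            "config_hash": self.config_hash,
            "seeds": seeds.issued,
            "records": self.records,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)
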