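"""Run configuration, named presets, and seed derivation.

Two presets ship:

``desk``
    A reduced-scale CPU configuration: 64x64 phantoms, 40 pairs per
    direction, 5 epochs, thinner networks, learning rate 1e-3.  Every test
    and the acceptance script run at this scale.
``paper``
    The full-scale study configuration: 256x256 images, 5500 pairs per
    direction, 100 epochs, learning rate 2e-4, first-layer channels 64
    (U-Net) / 32 (autoencoder).  Documented and runnable but guarded — it
    is GPU-scale work and is never run by the test suite.

Every random stage derives its seed from the global seed plus a stable
per-stage salt, so a run is reproducible from one integer.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .kspace import CorruptionConfig
from .models import AESpec, CGANSpec, TrainingConfig, UNetSpec
from .motion import MotionBankConfig
from .phantom import PhantomConfig
from .types import InvalidConfigError

__all__ = ["RunConfig", "derive_seed", "PRESETS"]


def derive_seed(base_seed: int, salt: str) -> int:
    """Stable per-stage seed below 2**31, derived from the global seed."""
    ss = np.random.SeedSequence([int(base_seed), zlib.crc32(salt.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    preset: str = "desk"
    seed: int = 0
    image_size: int = 64
    n_sources: int = 10
    n_pairs: int = 40
    n_tissue_regions: int = 5
    jitter: float = 0.05
    bank: MotionBankConfig = field(default_factory=MotionBankConfig)
    p_motion: float = 0.5
    etl: int = 13
    protect_center: int = 0
    train_frac: float = 0.9
    val_frac_of_train: float = 0.1
    epochs: int = 5
    learning_rate: float = 2e-3
    batch_size: int = 1
    clip_grad_norm: float | None = 1.0
    ae: AESpec = field(default_factory=lambda: AESpec(n_stacks=3, first_channels=16))
    unet: UNetSpec = field(default_factory=lambda: UNetSpec(depth=3, first_channels=16))
    cgan: CGANSpec = field(default_factory=lambda: CGANSpec(
        generator=UNetSpec(depth=3, first_channels=16, dropout_p=0.5,
                           use_batchnorm=True),
        disc_first_channels=8))

    def phantom_config(self, index: int) -> PhantomConfig:
        return PhantomConfig(
            size=self.image_size,
            seed=derive_seed(self.seed, f"phantom/{index}"),
            n_tissue_regions=self.n_tissue_regions,
            jitter=self.jitter,
        )

    def corruption_config(self, direction: str, seed: int) -> CorruptionConfig:
        return CorruptionConfig(p_motion=self.p_motion, seed=seed,
                                pe_direction=direction,
                                protect_center=self.protect_center)

    def training_config(self) -> TrainingConfig:
        return TrainingConfig(
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            epochs=self.epochs, seed=derive_seed(self.seed, "train"),
            image_size=self.image_size, clip_grad_norm=self.clip_grad_norm,
        )

    def spec_for(self, model_kind: str):
        return {"ae": self.ae, "unet": self.unet, "cgan": self.cgan}[model_kind]

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "bank" in d:
            d["bank"] = MotionBankConfig(**d["bank"])
        if "ae" in d:
            d["ae"] = AESpec(**d["ae"])
        if "unet" in d:
            d["unet"] = UNetSpec(**d["unet"])
        if "cgan" in d:
            c = dict(d["cgan"])
            c["generator"] = UNetSpec(**c["generator"])
            d["cgan"] = CGANSpec(**c)
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not 0.0 < self.train_frac < 1.0:
            raise InvalidConfigError("train_frac must lie in (0, 1)")
        if not 0.0 <= self.val_frac_of_train < 1.0:
            raise InvalidConfigError("val_frac_of_train must lie in [0, 1)")
        if not 0.0 <= self.p_motion <= 1.0:
            raise InvalidConfigError("p_motion must lie in [0, 1]")
        if self.n_pairs < 1 or self.n_sources < 1:
            raise InvalidConfigError("n_pairs and n_sources must be >= 1")


def _desk(seed: int = 0) -> RunConfig:
    return RunConfig(preset="desk", seed=seed)


def _paper(seed: int = 0) -> RunConfig:
    return RunConfig(
        preset="paper", seed=seed, image_size=256, n_sources=480, n_pairs=5500,
        epochs=100, learning_rate=2e-4,
        ae=AESpec(), unet=UNetSpec(), cgan=CGANSpec(),
    )


PRESETS = {"desk": _desk, "paper": _paper}
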