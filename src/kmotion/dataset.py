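"""Paired-dataset assembly: per-direction pools, splits, and normalization.

The study design trains a model per motion-direction condition.  For each
phase-encode direction a pool of (corrupted, clean) pairs is simulated;
90% of the pool becomes the training pool (of which 10% is carved off for
validation) and the rest is the test set — at a 5500-image pool this gives
exactly 4455 / 495 / 550.  A "both directions" model trains on equal halves
of the two single-direction training pools (2475 + 2475 = 4950).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kspace import CorruptionConfig, simulate_pair
from .motion import MotionBankConfig
from .types import (
    DegenerateNormalizationError,
    ImageGrid,
    InvalidConfigError,
    PairedSample,
)

__all__ = [
    "DatasetSplit",
    "build_direction_pool",
    "split_pool",
    "build_both_direction_split",
    "normalize_input",
    "denormalize_output",
    "save_split",
    "load_split",
]


@dataclass
class DatasetSplit:
    """Disjoint train / validation / test partition of a sample pool."""

    train: list[PairedSample]
    validation: list[PairedSample]
    test: list[PairedSample]
    direction_mode: str = "vertical"

    def __post_init__(self) -> None:
        keys = [s.key for subset in (self.train, self.validation, self.test) for s in subset]
        if len(keys) != len(set(keys)):
            raise InvalidConfigError("split subsets overlap by (provenance, seed)")

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.validation), len(self.test))

    def manifest(self) -> pd.DataFrame:
        rows = []
        for subset_name, subset in (
            ("train", self.train), ("validation", self.validation), ("test", self.test)
        ):
            for i, s in enumerate(subset):
                rows.append({
                    "subset": subset_name, "index": i, "provenance": s.provenance,
                    "seed": s.seed, "direction": s.direction,
                })
        return pd.DataFrame(rows)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def build_direction_pool(sources: list[ImageGrid], n_pairs: int, direction: str,
                         base_seed: int = 0,
                         bank_config: MotionBankConfig | None = None,
                         p_motion: float = 0.5, etl: int = 13,
                         protect_center: int = 0) -> list[PairedSample]:
    """Simulate ``n_pairs`` corruption pairs in one PE direction.

    Sources are cycled; every pair gets a distinct seed derived from
    ``base_seed`` so the pool is fully reproducible.
    """
    if not sources:
        raise InvalidConfigError("at least one source image is required")
    if n_pairs < 1:
        raise InvalidConfigError("n_pairs must be >= 1")
    seeds = np.random.SeedSequence(base_seed).generate_state(n_pairs) % (2**31)
    pool: list[PairedSample] = []
    for i in range(n_pairs):
        src = sources[i % len(sources)]
        cfg = CorruptionConfig(
            p_motion=p_motion, seed=int(seeds[i]), pe_direction=direction,
            protect_center=protect_center,
        )
        pool.append(simulate_pair(
            src, bank_config=bank_config, corruption_config=cfg, etl=etl,
            provenance=f"source_{i % len(sources):04d}",
        ))
    return pool


def split_pool(pool: list[PairedSample], train_frac: float = 0.9,
               val_frac_of_train: float = 0.1, seed: int = 0,
               direction_mode: str | None = None) -> DatasetSplit:
    """Seeded-shuffle split into train / validation / test.

    The training pool is round(train_frac * n) samples (round half away from
    zero); validation is round(val_frac_of_train * training pool) carved out
    of it; test is the remainder.  A 5500 pool yields 4455 / 495 / 550.
    """
    if not 0.0 < train_frac < 1.0:
        raise InvalidConfigError("train_frac must lie in (0, 1)")
    if not 0.0 <= val_frac_of_train < 1.0:
        raise InvalidConfigError("val_frac_of_train must lie in [0, 1)")
    n = len(pool)
    if n == 0:
        raise InvalidConfigError("cannot split an empty pool")
    n_train_pool = _round_half_away(train_frac * n)
    n_val = _round_half_away(val_frac_of_train * n_train_pool)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [pool[i] for i in order]
    train_pool = shuffled[:n_train_pool]
    test = shuffled[n_train_pool:]
    validation = train_pool[:n_val]
    train = train_pool[n_val:]
    mode = direction_mode or (pool[0].direction if pool else "vertical")
    return DatasetSplit(train=train, validation=validation, test=test,
                        direction_mode=mode)


def build_both_direction_split(h_split: DatasetSplit, v_split: DatasetSplit,
                               seed: int = 0,
                               val_frac_of_train: float = 0.1) -> DatasetSplit:
    """Combine equal halves of two single-direction splits.

    Each direction contributes the first half (after a seeded shuffle) of
    its train+validation pool, so two 4950-sample training pools combine
    into one of 4950 (2475 per direction).  Validation is re-carved from
    each half equally, keeping every subset direction-balanced; the test
    set is the union of the two direction-pure test sets.
    """
    if h_split.direction_mode == v_split.direction_mode:
        raise InvalidConfigError("inputs must come from different directions")
    rng = np.random.default_rng(seed)
    halves: list[list[PairedSample]] = []
    for split in (h_split, v_split):
        pool = split.train + split.validation
        order = rng.permutation(len(pool))
        half = [pool[i] for i in order[: len(pool) // 2]]
        halves.append(half)
    if len(halves[0]) != len(halves[1]):
        raise InvalidConfigError("direction pools must have matching sizes/fractions")
    train: list[PairedSample] = []
    validation: list[PairedSample] = []
    for half in halves:
        n_val = _round_half_away(val_frac_of_train * len(half))
        validation.extend(half[:n_val])
        train.extend(half[n_val:])
    test = list(h_split.test) + list(v_split.test)
    return DatasetSplit(train=train, validation=validation, test=test,
                        direction_mode="both")


def normalize_input(image: ImageGrid) -> ImageGrid:
    """Affine min-max normalization onto [0, 1] (the model input scale)."""
    px = image.pixels
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        raise DegenerateNormalizationError("cannot normalize a constant image (min = max)")
    return image.with_pixels((px - lo) / (hi - lo))


def denormalize_output(image: ImageGrid) -> ImageGrid:
    """Clip to [0, 1] then rescale onto [0, 255] (the model output scale)."""
    return image.with_pixels(np.clip(image.pixels, 0.0, 1.0) * 255.0)


# ---------------------------------------------------------------------------
# On-disk layout: <root>/<direction>/<subset>/{corrupted,clean}/NNNN.png


def save_split(split: DatasetSplit, root: str | Path, bit_depth: int = 16) -> Path:
    """Write all samples as PNG pairs plus a manifest.csv; returns manifest path."""
    from .phantom import save_png

    root = Path(root)
    rows = []
    for subset_name, subset in (
        ("train", split.train), ("validation", split.validation), ("test", split.test)
    ):
        for i, s in enumerate(subset):
            d = root / s.direction / subset_name
            for role, img in (("corrupted", s.corrupted), ("clean", s.clean)):
                (d / role).mkdir(parents=True, exist_ok=True)
                save_png(img, d / role / f"{i:04d}.png", bit_depth=bit_depth)
            rows.append({
                "subset": subset_name, "index": i, "direction": s.direction,
                "seed": s.seed, "provenance": s.provenance,
                "corrupted": str(Path(s.direction) / subset_name / "corrupted" / f"{i:04d}.png"),
                "clean": str(Path(s.direction) / subset_name / "clean" / f"{i:04d}.png"),
            })
    manifest = root / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_split(root: str | Path, direction_mode: str = "vertical") -> DatasetSplit:
    """Rebuild a DatasetSplit from a save_split() directory."""
    from .phantom import load_image

    root = Path(root)
    df = pd.read_csv(root / "manifest.csv")
    subsets: dict[str, list[PairedSample]] = {"train": [], "validation": [], "test": []}
    for _, row in df.iterrows():
        corrupted = load_image(root / row["corrupted"])
        clean = load_image(root / row["clean"])
        subsets[row["subset"]].append(PairedSample(
            corrupted=ImageGrid(corrupted.pixels, pe_axis=row["direction"]),
            clean=ImageGrid(clean.pixels, pe_axis=row["direction"]),
            direction=row["direction"], seed=int(row["seed"]),
            provenance=str(row["provenance"]),
        ))
    return DatasetSplit(train=subsets["train"], validation=subsets["validation"],
                        test=subsets["test"], direction_mode=direction_mode)
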