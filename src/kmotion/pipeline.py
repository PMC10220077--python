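"""High-level pipeline steps shared by the CLI and the acceptance script."""

from __future__ import annotations

import time
from pathlib import Path

from . import models as md
from .config import RunConfig, derive_seed
from .dataset import (
    DatasetSplit,
    build_both_direction_split,
    build_direction_pool,
    split_pool,
)
from .phantom import generate_phantom
from .types import ImageGrid

__all__ = ["make_sources", "simulate_direction_split", "simulate_splits", "train_model"]


def make_sources(cfg: RunConfig) -> list[ImageGrid]:
    """Generate the pool of synthetic source (clean) images."""
    return [generate_phantom(cfg.phantom_config(i)) for i in range(cfg.n_sources)]


def simulate_direction_split(cfg: RunConfig, sources: list[ImageGrid],
                             direction: str) -> DatasetSplit:
    pool = build_direction_pool(
        sources, cfg.n_pairs, direction,
        base_seed=derive_seed(cfg.seed, f"pool/{direction}"),
        bank_config=cfg.bank, p_motion=cfg.p_motion, etl=cfg.etl,
        protect_center=cfg.protect_center,
    )
    return split_pool(pool, cfg.train_frac, cfg.val_frac_of_train,
                      seed=derive_seed(cfg.seed, f"split/{direction}"))


def simulate_splits(cfg: RunConfig) -> dict[str, DatasetSplit]:
    """Per-direction splits plus the combined both-direction split."""
    sources = make_sources(cfg)
    h = simulate_direction_split(cfg, sources, "horizontal")
    v = simulate_direction_split(cfg, sources, "vertical")
    both = build_both_direction_split(h, v, seed=derive_seed(cfg.seed, "split/both"),
                                      val_frac_of_train=cfg.val_frac_of_train)
    return {"horizontal": h, "vertical": v, "both": both}


def train_model(cfg: RunConfig, split: DatasetSplit, model_kind: str,
                log_fn=None) -> md.TrainedModel:
    t0 = time.perf_counter()
    trained = md.train(model_kind, split, cfg.training_config(),
                       spec=cfg.spec_for(model_kind), log_fn=log_fn)
    if log_fn:
        log_fn(f"[{model_kind}] trained in {time.perf_counter() - t0:.1f}s")
    return trained
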