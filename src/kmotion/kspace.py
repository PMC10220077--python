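"""k-space motion-artefact simulation for a fast spin-echo acquisition.

A fast spin-echo sequence acquires ``etl`` (echo train length) phase-encode
lines per repetition (TR).  Head motion is modelled as happening between
TRs: each TR block of k-space lines is filled either from the still source
image or from one rigidly transformed copy drawn from a motion bank.
Re-assembling the mixed lines and inverse-transforming the result yields the
characteristic ghosting along the phase-encode axis.

Conventions: k-space is centered (fftshifted; line 0 carries the most
negative spatial frequency) and reconstruction returns the complex
magnitude, the standard MRI magnitude image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motion import MotionBank, MotionBankConfig, build_motion_bank
from .types import ImageGrid, InvalidConfigError, PairedSample, ShapeError

__all__ = [
    "STILL",
    "KSpaceGrid",
    "EchoTrainSchedule",
    "MotionTimeline",
    "CorruptionConfig",
    "to_kspace",
    "from_kspace",
    "make_echo_train_schedule",
    "sample_motion_timeline",
    "corrupt_image",
    "simulate_pair",
]

#: Timeline sentinel: the TR block uses the original (motion-free) lines.
STILL = -1


@dataclass
class KSpaceGrid:
    """Centered 2-D k-space samples of an image.

    ``pe_axis`` names the image axis along which ghosting runs; phase-encode
    lines are indexed along array axis 0 for ``"vertical"`` and axis 1 for
    ``"horizontal"``.
    """

    values: np.ndarray
    pe_axis: str = "vertical"
    centered: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2:
            raise ShapeError(f"KSpaceGrid requires a 2-D array, got {self.values.shape}")

    @property
    def n_pe(self) -> int:
        """Number of phase-encode lines."""
        axis = 0 if self.pe_axis == "vertical" else 1
        return int(self.values.shape[axis])

    def line(self, index: int) -> np.ndarray:
        if self.pe_axis == "vertical":
            return self.values[index, :]
        return self.values[:, index]

    def set_line(self, index: int, data: np.ndarray) -> None:
        if self.pe_axis == "vertical":
            self.values[index, :] = data
        else:
            self.values[:, index] = data


@dataclass
class EchoTrainSchedule:
    """Partition of phase-encode lines into TR blocks of length ``etl``."""

    n_pe: int
    etl: int
    blocks: list[list[int]]

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block_of_line(self, line: int) -> int:
        for b, lines in enumerate(self.blocks):
            if line in lines:
                return b
        raise KeyError(line)


@dataclass
class MotionTimeline:
    """Per-TR-block source choice: STILL or a motion-bank entry index."""

    choices: list[int]

    def __len__(self) -> int:
        return len(self.choices)

    @property
    def n_corrupted(self) -> int:
        return sum(1 for c in self.choices if c != STILL)


@dataclass
class CorruptionConfig:
    """Randomized per-TR corruption policy.

    ``p_motion`` is the probability that any one TR block takes its lines
    from a (uniformly chosen) motion-bank image instead of the still image.
    ``protect_center`` forces that many central k-space lines to STILL.
    """

    p_motion: float = 0.5
    seed: int = 0
    pe_direction: str = "vertical"
    protect_center: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.p_motion <= 1.0:
            raise InvalidConfigError("p_motion must lie in [0, 1]")
        if self.protect_center < 0:
            raise InvalidConfigError("protect_center must be >= 0")
        if self.pe_direction not in ("horizontal", "vertical"):
            raise InvalidConfigError("pe_direction must be horizontal or vertical")


# ---------------------------------------------------------------------------
# Fourier transforms


def to_kspace(image: ImageGrid) -> KSpaceGrid:
    """Forward 2-D DFT (unnormalized), fftshifted so DC sits at the center."""
    k = np.fft.fftshift(np.fft.fft2(image.pixels))
    return KSpaceGrid(values=k, pe_axis=image.pe_axis, centered=True)


def from_kspace(k: KSpaceGrid) -> ImageGrid:
    """Inverse DFT followed by the complex magnitude (MRI magnitude image)."""
    if not np.all(np.isfinite(k.values)):
        raise ValueError("k-space contains non-finite entries")
    values = np.fft.ifftshift(k.values) if k.centered else k.values
    img = np.abs(np.fft.ifft2(values))
    return ImageGrid(pixels=img, pe_axis=k.pe_axis)


# ---------------------------------------------------------------------------
# Scheduling and corruption


def make_echo_train_schedule(n_pe: int, etl: int = 13,
                             ordering: str = "linear") -> EchoTrainSchedule:
    """Partition lines 0..n_pe-1 into TR blocks of ``etl`` lines each.

    ``linear`` fills blocks with consecutive lines; ``interleaved`` assigns
    line i to block i mod n_blocks.  The final linear block may be short
    (256 lines at etl 13 -> 19 full blocks and one of 9).
    """
    if etl <= 0:
        raise InvalidConfigError(f"etl must be positive, got {etl}")
    if etl > n_pe:
        raise InvalidConfigError(f"etl ({etl}) cannot exceed n_pe ({n_pe})")
    n_blocks = -(-n_pe // etl)  # ceil
    if ordering == "linear":
        blocks = [list(range(b * etl, min((b + 1) * etl, n_pe))) for b in range(n_blocks)]
    elif ordering == "interleaved":
        blocks = [list(range(b, n_pe, n_blocks)) for b in range(n_blocks)]
    else:
        raise InvalidConfigError(f"unknown ordering {ordering!r}")
    return EchoTrainSchedule(n_pe=n_pe, etl=etl, blocks=blocks)


def sample_motion_timeline(schedule: EchoTrainSchedule, bank_size: int,
                           config: CorruptionConfig) -> MotionTimeline:
    """Draw the per-TR source: STILL w.p. 1 - p_motion, else a uniform bank index.

    Deterministic for a fixed seed.  Blocks covering protected central
    k-space lines are forced to STILL after the draw (the random stream is
    unaffected by protection).
    """
    config.validate()
    if bank_size < 1 and config.p_motion > 0:
        raise InvalidConfigError("bank_size must be >= 1 when p_motion > 0")
    rng = np.random.default_rng(config.seed)
    choices: list[int] = []
    for _ in range(schedule.n_blocks):
        if rng.random() < config.p_motion:
            choices.append(int(rng.integers(bank_size)))
        else:
            choices.append(STILL)
    if config.protect_center > 0:
        start = (schedule.n_pe - config.protect_center) // 2
        protected = set(range(start, start + config.protect_center))
        for b, lines in enumerate(schedule.blocks):
            if protected.intersection(lines):
                choices[b] = STILL
    return MotionTimeline(choices=choices)


def assemble_kspace(original: ImageGrid, bank: MotionBank, schedule: EchoTrainSchedule,
                    timeline: MotionTimeline, pe_direction: str | None = None) -> KSpaceGrid:
    """Mix k-space lines TR block by TR block into one corrupted k-space.

    Each block's phase-encode lines are copied verbatim from the k-space of
    the timeline's chosen source; STILL blocks keep the original's lines
    bitwise unchanged.
    """
    pe = pe_direction or original.pe_axis
    if len(timeline) != schedule.n_blocks:
        raise InvalidConfigError("timeline length must equal the number of TR blocks")
    src = ImageGrid(pixels=original.pixels, pe_axis=pe)
    k_out = to_kspace(src)
    expected_n_pe = src.shape[0] if pe == "vertical" else src.shape[1]
    if schedule.n_pe != expected_n_pe:
        raise ShapeError(
            f"schedule covers {schedule.n_pe} lines but image has {expected_n_pe} along {pe}"
        )

    k_cache: dict[int, KSpaceGrid] = {}
    for block_lines, choice in zip(schedule.blocks, timeline.choices):
        if choice == STILL:
            continue
        if choice not in k_cache:
            entry = bank.image(choice)
            if entry.shape != original.shape:
                raise ShapeError("bank entry shape differs from the original image")
            k_cache[choice] = to_kspace(ImageGrid(pixels=entry.pixels, pe_axis=pe))
        k_src = k_cache[choice]
        for line in block_lines:
            k_out.set_line(line, k_src.line(line))
    return k_out


def corrupt_image(original: ImageGrid, bank: MotionBank, schedule: EchoTrainSchedule,
                  timeline: MotionTimeline, pe_direction: str | None = None) -> ImageGrid:
    """Ghosted image: magnitude reconstruction of the mixed k-space."""
    return from_kspace(assemble_kspace(original, bank, schedule, timeline, pe_direction))


def simulate_pair(original: ImageGrid, bank_config: MotionBankConfig | None = None,
                  corruption_config: CorruptionConfig | None = None,
                  etl: int = 13, ordering: str = "linear",
                  provenance: str = "") -> PairedSample:
    """Build the bank from ``original`` and produce one (corrupted, clean) pair.

    All randomness flows through ``corruption_config.seed``; the same seed
    reproduces the identical corrupted image.
    """
    bank_config = bank_config or MotionBankConfig()
    cfg = corruption_config or CorruptionConfig()
    cfg.validate()
    bank = build_motion_bank(original, bank_config)
    n_pe = original.shape[0] if cfg.pe_direction == "vertical" else original.shape[1]
    schedule = make_echo_train_schedule(n_pe, etl=etl, ordering=ordering)
    timeline = sample_motion_timeline(schedule, len(bank), cfg)
    corrupted = corrupt_image(original, bank, schedule, timeline, cfg.pe_direction)
    clean = ImageGrid(pixels=original.pixels.copy(), pe_axis=cfg.pe_direction)
    return PairedSample(
        corrupted=corrupted, clean=clean, direction=cfg.pe_direction,
        seed=cfg.seed, provenance=provenance,
    )
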