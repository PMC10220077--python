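"""Rigid-motion bank: shifted and rotated copies of a source image.

The simulated head motion is rigid and in-plane.  From one source image a
"bank" of transformed copies is built: integer-pixel translations up to
±max_shift along the vertical, horizontal and diagonal directions, and
rotations up to ±max_rot about the image center.  With the default grid
(±10 px step 1, ±5° step 0.5°) the bank holds 80 entries — 20 per
translation direction plus 20 rotations.  Corrupted k-space lines are later
drawn from these images.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .types import ImageGrid, InvalidConfigError

__all__ = [
    "RigidMotionParams",
    "MotionBankConfig",
    "MotionBank",
    "translate_image",
    "rotate_image",
    "build_motion_bank",
    "export_motion_bank",
]

TRANSLATION_KINDS = ("translation_vertical", "translation_horizontal", "translation_diagonal")


@dataclass(frozen=True)
class RigidMotionParams:
    """One rigid in-plane transform: integer shift (dx right, dy down) or rotation."""

    dx: int = 0
    dy: int = 0
    theta: float = 0.0
    kind: str = "translation_vertical"

    def __post_init__(self) -> None:
        if self.kind in TRANSLATION_KINDS:
            if self.theta != 0.0:
                raise InvalidConfigError("translation kinds must have theta = 0")
            if self.kind == "translation_diagonal" and abs(self.dx) != abs(self.dy):
                raise InvalidConfigError("diagonal translations require |dx| = |dy|")
        elif self.kind == "rotation":
            if self.dx != 0 or self.dy != 0:
                raise InvalidConfigError("rotation kind must have dx = dy = 0")
        else:
            raise InvalidConfigError(f"unknown motion kind {self.kind!r}")


@dataclass
class MotionBankConfig:
    """Transform grid: shifts {±step..±max_shift}, angles {±rot_step..±max_rot}."""

    max_shift: int = 10
    shift_step: int = 1
    max_rot: float = 5.0
    rot_step: float = 0.5

    def validate(self) -> None:
        if self.max_shift < 0 or self.shift_step <= 0:
            raise InvalidConfigError("max_shift >= 0 and shift_step > 0 required")
        if self.max_shift % self.shift_step != 0:
            raise InvalidConfigError("max_shift must be a multiple of shift_step")
        if self.max_rot < 0 or (self.max_rot > 0 and self.rot_step <= 0):
            raise InvalidConfigError("max_rot >= 0 and rot_step > 0 required")
        if self.max_rot > 0:
            ratio = self.max_rot / self.rot_step
            if abs(ratio - round(ratio)) > 1e-9:
                raise InvalidConfigError("max_rot / rot_step must be an integer")
        if self.max_shift == 0 and self.max_rot == 0:
            raise InvalidConfigError("degenerate config: no shifts and no rotations")

    @property
    def n_entries(self) -> int:
        n_shift = self.max_shift // self.shift_step
        n_rot = int(round(self.max_rot / self.rot_step)) if self.max_rot > 0 else 0
        return 3 * 2 * n_shift + 2 * n_rot


@dataclass
class MotionBank:
    source: ImageGrid
    entries: list[tuple[RigidMotionParams, ImageGrid]]

    def __len__(self) -> int:
        return len(self.entries)

    def image(self, index: int) -> ImageGrid:
        return self.entries[index][1]

    def params(self, index: int) -> RigidMotionParams:
        return self.entries[index][0]


def translate_image(image: ImageGrid, dx: int, dy: int, mode: str = "zero") -> ImageGrid:
    """Shift by whole pixels: dx > 0 moves content right, dy > 0 down.

    ``mode="zero"`` (default) fills the vacated border with 0 — the
    physically sensible choice for head MRI where the border is air.
    ``mode="wrap"`` rolls circularly (used for Fourier shift-theorem checks).
    """
    h, w = image.shape
    if abs(dx) >= w or abs(dy) >= h:
        raise InvalidConfigError(
            f"shift ({dx}, {dy}) magnitude must be smaller than image size {image.shape}"
        )
    dx, dy = int(dx), int(dy)
    out = np.roll(image.pixels, shift=(dy, dx), axis=(0, 1))
    if mode == "zero":
        if dy > 0:
            out[:dy, :] = 0.0
        elif dy < 0:
            out[dy:, :] = 0.0
        if dx > 0:
            out[:, :dx] = 0.0
        elif dx < 0:
            out[:, dx:] = 0.0
    elif mode != "wrap":
        raise InvalidConfigError(f"unknown boundary mode {mode!r}")
    return image.with_pixels(out)


def rotate_image(image: ImageGrid, theta: float) -> ImageGrid:
    """Rotate counter-clockwise by ``theta`` degrees about the grid center.

    Bilinear interpolation, zero fill outside the source support; the
    rotation center is ((H-1)/2, (W-1)/2) in 0-based pixel coordinates.
    """
    if not np.isfinite(theta):
        raise InvalidConfigError("theta must be finite")
    if abs(theta) > 45:
        raise InvalidConfigError("|theta| must be <= 45 degrees")
    out = ndimage.rotate(
        image.pixels, angle=theta, reshape=False, order=1, mode="constant",
        cval=0.0, prefilter=False,
    )
    return image.with_pixels(out)


def _signed_grid(max_val: float, step: float) -> list[float]:
    n = int(round(max_val / step))
    return [s * step for s in range(-n, n + 1) if s != 0]


def build_motion_bank(image: ImageGrid, config: MotionBankConfig | None = None) -> MotionBank:
    """Enumerate all bank transforms of ``image`` in deterministic order.

    Ordering: vertical, horizontal then diagonal translations (each
    ascending by signed shift), then rotations ascending by signed angle.
    The identity transform is excluded.
    """
    config = config or MotionBankConfig()
    config.validate()
    entries: list[tuple[RigidMotionParams, ImageGrid]] = []
    shifts = [int(s) for s in _signed_grid(config.max_shift, config.shift_step)]
    for s in shifts:
        p = RigidMotionParams(dx=0, dy=s, kind="translation_vertical")
        entries.append((p, translate_image(image, 0, s)))
    for s in shifts:
        p = RigidMotionParams(dx=s, dy=0, kind="translation_horizontal")
        entries.append((p, translate_image(image, s, 0)))
    for s in shifts:
        p = RigidMotionParams(dx=s, dy=s, kind="translation_diagonal")
        entries.append((p, translate_image(image, s, s)))
    if config.max_rot > 0:
        for a in _signed_grid(config.max_rot, config.rot_step):
            p = RigidMotionParams(theta=a, kind="rotation")
            entries.append((p, rotate_image(image, a)))
    return MotionBank(source=image, entries=entries)


def export_motion_bank(bank: MotionBank, out_dir: str | Path, bit_depth: int = 16) -> Path:
    """Write bank entries as PNGs plus a CSV manifest; returns the manifest path."""
    from .phantom import save_png

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "kind", "dx", "dy", "theta", "filename"])
        for i, (p, img) in enumerate(bank.entries):
            fname = f"entry_{i:04d}.png"
            save_png(img, out_dir / fname, bit_depth=bit_depth)
            writer.writerow([i, p.kind, p.dx, p.dy, p.theta, fname])
    return manifest
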