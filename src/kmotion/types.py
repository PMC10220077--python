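"""Core domain types shared across the package.

The central object is :class:`ImageGrid`, a 2-D real-valued intensity image
carrying explicit phase-encode axis semantics: in MRI, k-space lines are
acquired one per readout, and inconsistencies between lines produce ghosting
along the phase-encode (PE) axis.  ``pe_axis`` records the image axis along
which that ghosting runs ("vertical" = image rows, "horizontal" = columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PE_AXES",
    "ImageGrid",
    "PairedSample",
    "InvalidConfigError",
    "FormatError",
    "ShapeError",
    "DegenerateNormalizationError",
    "LeakageError",
]

PE_AXES = ("horizontal", "vertical")


class InvalidConfigError(ValueError):
    """A configuration value violates its documented constraints."""


class FormatError(ValueError):
    """An on-disk image could not be read under the named standard."""


class ShapeError(ValueError):
    """Array shapes are incompatible with the requested operation."""


class DegenerateNormalizationError(ValueError):
    """Min-max normalization was requested on a constant image."""


class LeakageError(RuntimeError):
    """Train and test sets share samples (by provenance + seed)."""


@dataclass
class ImageGrid:
    """A 2-D real intensity image with an explicit phase-encode axis.

    Parameters
    ----------
    pixels:
        2-D float array of finite intensities (arbitrary units).
    pe_axis:
        ``"vertical"`` (ghosting along rows, k-space lines indexed by row)
        or ``"horizontal"`` (ghosting along columns).
    """

    pixels: np.ndarray
    pe_axis: str = "vertical"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ShapeError(
                f"ImageGrid requires a 2-D array, got shape {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("ImageGrid intensities must all be finite")
        if self.pe_axis not in PE_AXES:
            raise InvalidConfigError(f"pe_axis must be one of {PE_AXES}, got {self.pe_axis!r}")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def with_pixels(self, pixels: np.ndarray) -> "ImageGrid":
        """A copy of this grid with new pixel data, same PE axis."""
        return ImageGrid(pixels=pixels, pe_axis=self.pe_axis)

    def transposed(self) -> "ImageGrid":
        """Transpose the grid, swapping the PE axis label accordingly."""
        other = "horizontal" if self.pe_axis == "vertical" else "vertical"
        return ImageGrid(pixels=self.pixels.T.copy(), pe_axis=other)


@dataclass
class PairedSample:
    """One supervised (corrupted, clean) training pair.

    ``direction`` is the PE axis along which the corruption ghosts;
    ``seed`` reproduces the corruption; ``provenance`` identifies the
    source image the pair was derived from.
    """

    corrupted: ImageGrid
    clean: ImageGrid
    direction: str
    seed: int = 0
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.corrupted.shape != self.clean.shape:
            raise ShapeError("corrupted and clean images must share a shape")
        if self.direction not in PE_AXES:
            raise InvalidConfigError(f"direction must be one of {PE_AXES}")

    @property
    def key(self) -> tuple[str, int]:
        """Identity used for split disjointness and leakage checks."""
        return (self.provenance, self.seed)
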