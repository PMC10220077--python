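"""Synthetic head phantoms and real-image I/O.

The phantom generator composes concentric ellipses into a head-like 2-D
image at T2-ish contrast: a bright scalp rim, mid-gray brain parenchyma,
bright CSF-filled ventricles, and two bright anterior eyeballs over a dark
(air) background.  It exists so the whole simulation / training pipeline is
exercisable without any acquired MRI data; readers for PNG, NIfTI and
single-frame DICOM cover the real-data path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .types import FormatError, ImageGrid, InvalidConfigError

__all__ = [
    "PhantomConfig",
    "generate_phantom",
    "load_image",
    "load_images",
    "save_png",
]


@dataclass
class PhantomConfig:
    """Parameters for one synthetic head phantom.

    ``jitter`` randomizes ellipse centers (fraction of image size) and
    intensities (fraction of the intensity range) so repeated phantoms from
    different seeds emulate different subjects/slices.
    ``n_tissue_regions`` guarantees at least that many distinct
    piecewise-constant intensity levels inside the head.
    """

    size: int = 256
    seed: int = 0
    n_tissue_regions: int = 4
    intensity_range: tuple[float, float] = (0.0, 255.0)
    jitter: float = 0.05

    def validate(self) -> None:
        if self.size < 32:
            raise InvalidConfigError(f"phantom size must be >= 32, got {self.size}")
        lo, hi = self.intensity_range
        if not lo < hi:
            raise InvalidConfigError("intensity_range must satisfy min < max")
        if self.n_tissue_regions < 2:
            raise InvalidConfigError("n_tissue_regions must be >= 2")
        if self.jitter < 0:
            raise InvalidConfigError("jitter must be >= 0")


def _ellipse_mask(size: int, cy: float, cx: float, ry: float, rx: float,
                  rr: np.ndarray, cc: np.ndarray) -> np.ndarray:
    return ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0


def generate_phantom(config: PhantomConfig) -> ImageGrid:
    """Deterministically render a head-like ellipse-composite phantom.

    Same config (including seed) -> bitwise-identical image.  The background
    outside the head is the minimum of ``intensity_range``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    s = config.size
    lo, hi = config.intensity_range
    span = hi - lo
    j = config.jitter

    def jit(scale: float) -> float:
        return float(rng.uniform(-j, j)) * scale

    rr, cc = np.mgrid[0:s, 0:s].astype(np.float64)
    img = np.full((s, s), lo, dtype=np.float64)

    cy = s * (0.5 + jit(1.0))
    cx = s * (0.5 + jit(1.0))
    head_ry = s * (0.42 + jit(0.3))
    head_rx = s * (0.34 + jit(0.3))

    # scalp/fat rim (bright on T2), skull left implicit in the rim band
    rim = _ellipse_mask(s, cy, cx, head_ry, head_rx, rr, cc)
    img[rim] = lo + span * (0.95 + jit(0.5))

    # brain parenchyma
    brain = _ellipse_mask(s, cy, cx, head_ry * 0.90, head_rx * 0.88, rr, cc)
    img[brain] = lo + span * (0.45 + jit(0.5))

    # lateral ventricles: CSF, bright on T2
    vent_level = lo + span * (0.85 + jit(0.5))
    for side in (-1.0, 1.0):
        vent = _ellipse_mask(
            s,
            cy - 0.02 * s + jit(1.0) * 0.3,
            cx + side * (0.07 * s) + jit(1.0) * 0.3,
            0.12 * s, 0.035 * s, rr, cc,
        )
        img[vent & brain] = vent_level

    # eyeballs: vitreous, bright, anterior (top of the image)
    eye_level = lo + span * (1.0 + jit(0.2))
    for side in (-1.0, 1.0):
        eye = _ellipse_mask(
            s,
            cy - head_ry * 1.08,
            cx + side * (0.13 * s) + jit(1.0) * 0.3,
            0.05 * s, 0.05 * s, rr, cc,
        )
        img[eye] = eye_level

    # extra random tissue blobs if more distinct regions were requested
    n_base = 4  # rim, parenchyma, ventricles, eyeballs
    for _ in range(max(0, config.n_tissue_regions - n_base)):
        blob = _ellipse_mask(
            s,
            cy + rng.uniform(-0.18, 0.18) * s,
            cx + rng.uniform(-0.14, 0.14) * s,
            rng.uniform(0.03, 0.08) * s,
            rng.uniform(0.03, 0.08) * s,
            rr, cc,
        )
        img[blob & brain] = lo + span * rng.uniform(0.2, 0.8)

    np.clip(img, lo, hi, out=img)
    return ImageGrid(pixels=img)


# ---------------------------------------------------------------------------
# I/O


def save_png(image: ImageGrid, path: str | Path, bit_depth: int = 16,
             sidecar: dict | None = None) -> None:
    """Write a grayscale PNG (8- or 16-bit) plus an optional JSON sidecar.

    Intensities are affinely mapped from the image's [min, max] onto the
    full integer range of the chosen bit depth; the sidecar records the
    original min/max so the mapping is invertible.
    """
    from PIL import Image

    if bit_depth not in (8, 16):
        raise InvalidConfigError("bit_depth must be 8 or 16")
    px = image.pixels
    lo, hi = float(px.min()), float(px.max())
    scale = (hi - lo) or 1.0
    maxval = (1 << bit_depth) - 1
    q = np.round((px - lo) / scale * maxval)
    if bit_depth == 8:
        pil = Image.fromarray(q.astype(np.uint8), mode="L")
    else:
        pil = Image.fromarray(q.astype(np.uint16))
    path = Path(path)
    pil.save(path, format="PNG")
    meta = {"min": lo, "max": hi, "bit_depth": bit_depth, "pe_axis": image.pe_axis}
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def _detect_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".dcm", ".dicom")):
        return "dicom"
    if name.endswith(".png"):
        return "png"
    raise FormatError(f"cannot infer image format from {path}")


def load_images(path: str | Path, format: str | None = None) -> list[ImageGrid]:
    """Read an image file into one ImageGrid per 2-D slice.

    PNG and single-frame DICOM yield one grid; a NIfTI volume yields one
    grid per axial slice (slicing along the last axis, 0-based).
    If a JSON sidecar written by :func:`save_png` is present its recorded
    min/max are used to undo the quantization mapping.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    fmt = format or _detect_format(path)

    if fmt == "png":
        from PIL import Image

        with Image.open(path) as pil:
            if pil.mode in ("RGB", "RGBA", "P"):
                raise FormatError(f"expected grayscale PNG, got mode {pil.mode}: {path}")
            arr = np.asarray(pil, dtype=np.float64)
        sidecar = path.with_suffix(".json")
        pe_axis = "vertical"
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            maxval = (1 << meta.get("bit_depth", 16)) - 1
            arr = arr / maxval * (meta["max"] - meta["min"]) + meta["min"]
            pe_axis = meta.get("pe_axis", "vertical")
        return [ImageGrid(pixels=arr, pe_axis=pe_axis)]

    if fmt == "nifti":
        import nibabel as nib

        vol = np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)
        if vol.ndim == 2:
            return [ImageGrid(pixels=vol)]
        if vol.ndim != 3:
            raise FormatError(f"expected a 2-D or 3-D NIfTI, got ndim={vol.ndim}: {path}")
        return [ImageGrid(pixels=vol[:, :, k]) for k in range(vol.shape[2])]

    if fmt == "dicom":
        import pydicom

        ds = pydicom.dcmread(str(path))
        arr = np.asarray(ds.pixel_array, dtype=np.float64)
        if arr.ndim != 2:
            raise FormatError(f"expected a single-frame DICOM, got shape {arr.shape}: {path}")
        return [ImageGrid(pixels=arr)]

    raise FormatError(f"unknown image format {fmt!r}")


def load_image(path: str | Path, format: str | None = None) -> ImageGrid:
    """Read a single 2-D image; errors on multi-slice volumes."""
    grids = load_images(path, format=format)
    if len(grids) != 1:
        raise FormatError(
            f"{path} contains {len(grids)} slices; use load_images() for volumes"
        )
    return grids[0]
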