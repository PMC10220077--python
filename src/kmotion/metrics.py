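"""Global SSIM and PSNR image-quality metrics.

SSIM is computed from *global* image statistics (no sliding window):

    SSIM(X, Y) = (2 mu_X mu_Y + C1)(2 s_X s_Y + C2)
                 / ((mu_X^2 + mu_Y^2 + C1)(s_X^2 + s_Y^2 + C2))

where in ``paper_global`` mode the cross term is literally 2*s_X*s_Y with
s the per-image standard deviation, and in ``standard_covariance`` mode the
cross term is 2*cov(X, Y) + C2 (the usual structural form).  Two constant
sets are available: the default C1 = (0.01*2000)^2 = 400 and
C2 = (0.03*2000)^2 = 3600, or a 255-dynamic-range set.

PSNR uses the peak of the *first* argument X (the corrupted or corrected
image): PSNR = 10 log10(max|X|^2 / MSE(X, Y)).  It is therefore not
symmetric in its arguments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ImageGrid, ShapeError

__all__ = [
    "SSIMConstants",
    "BatchMetrics",
    "mse",
    "psnr",
    "ssim",
    "batch_metrics",
]


@dataclass(frozen=True)
class SSIMConstants:
    """Regularization constants of the SSIM formula."""

    C1: float = (0.01 * 2000) ** 2
    C2: float = (0.03 * 2000) ** 2

    @staticmethod
    def from_dynamic_range(dynamic_range: float = 255.0) -> "SSIMConstants":
        return SSIMConstants(C1=(0.01 * dynamic_range) ** 2,
                             C2=(0.03 * dynamic_range) ** 2)


def _pixels(x: ImageGrid | np.ndarray) -> np.ndarray:
    return x.pixels if isinstance(x, ImageGrid) else np.asarray(x, dtype=np.float64)


def _check_shapes(X: np.ndarray, Y: np.ndarray) -> None:
    if X.shape != Y.shape:
        raise ShapeError(f"shape mismatch: {X.shape} vs {Y.shape}")


def mse(X: ImageGrid | np.ndarray, Y: ImageGrid | np.ndarray) -> float:
    """Mean over all pixels of the squared intensity difference."""
    Xp, Yp = _pixels(X), _pixels(Y)
    _check_shapes(Xp, Yp)
    return float(np.mean((Xp - Yp) ** 2))


def psnr(X: ImageGrid | np.ndarray, Y: ImageGrid | np.ndarray,
         peak: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB; the peak is max|X| unless overridden.

    Identical images return ``math.inf``.  A fixed ``peak`` (e.g. 255)
    enables cross-tool comparison.
    """
    Xp, Yp = _pixels(X), _pixels(Y)
    _check_shapes(Xp, Yp)
    err = mse(Xp, Yp)
    pk = float(np.max(np.abs(Xp))) if peak is None else float(peak)
    if err == 0.0:
        return math.inf
    if pk == 0.0:
        raise ValueError("PSNR undefined: zero-peak image with nonzero MSE")
    return 10.0 * math.log10(pk * pk / err)


def ssim(X: ImageGrid | np.ndarray, Y: ImageGrid | np.ndarray,
         constants: SSIMConstants | None = None,
         mode: str = "paper_global") -> float:
    """Global-statistics structural similarity of an image pair.

    ``paper_global`` uses 2*s_X*s_Y as the cross term (s = standard
    deviation, population convention); ``standard_covariance`` replaces it
    with 2*cov(X, Y).  Both reduce to 1 for identical images.
    """
    Xp, Yp = _pixels(X), _pixels(Y)
    _check_shapes(Xp, Yp)
    c = constants or SSIMConstants()
    mu_x, mu_y = float(Xp.mean()), float(Yp.mean())
    var_x = float(Xp.var())
    var_y = float(Yp.var())
    s_x, s_y = math.sqrt(var_x), math.sqrt(var_y)
    if mode == "paper_global":
        cross = 2.0 * s_x * s_y
    elif mode == "standard_covariance":
        cross = 2.0 * float(np.mean((Xp - mu_x) * (Yp - mu_y)))
    else:
        raise ValueError(f"unknown SSIM mode {mode!r}")
    num = (2.0 * mu_x * mu_y + c.C1) * (cross + c.C2)
    den = (mu_x**2 + mu_y**2 + c.C1) * (var_x + var_y + c.C2)
    return num / den


@dataclass
class BatchMetrics:
    """Per-pair SSIM/PSNR plus mean and sample standard deviation."""

    ssim_values: list[float]
    psnr_values: list[float]
    ssim_mean: float
    ssim_sd: float
    psnr_mean: float
    psnr_sd: float
    n: int
    sd_degenerate: bool = False  # single pair: SD reported as 0 with this flag

    def to_frame(self) -> pd.DataFrame:
        """One row per pair plus a summary row, ready for CSV export."""
        rows = [
            {"pair": i, "ssim": s, "psnr": p}
            for i, (s, p) in enumerate(zip(self.ssim_values, self.psnr_values))
        ]
        rows.append({"pair": "mean±sd",
                     "ssim": f"{self.ssim_mean:.4f}±{self.ssim_sd:.4f}",
                     "psnr": f"{self.psnr_mean:.4f}±{self.psnr_sd:.4f}"})
        return pd.DataFrame(rows)


def batch_metrics(pairs: list[tuple[ImageGrid | np.ndarray, ImageGrid | np.ndarray]],
                  constants: SSIMConstants | None = None,
                  mode: str = "paper_global",
                  peak: float | None = None) -> BatchMetrics:
    """Evaluate SSIM and PSNR over (candidate, reference) pairs.

    Standard deviations use the sample (n-1) convention; with a single
    pair SD is reported as 0 and flagged degenerate.
    """
    if not pairs:
        raise ValueError("batch_metrics requires at least one pair")
    ssims = [ssim(x, y, constants=constants, mode=mode) for x, y in pairs]
    psnrs = [psnr(x, y, peak=peak) for x, y in pairs]
    n = len(pairs)
    degenerate = n < 2
    ssim_sd = 0.0 if degenerate else float(np.std(ssims, ddof=1))
    finite = [p for p in psnrs if math.isfinite(p)]
    psnr_sd = float(np.std(finite, ddof=1)) if len(finite) >= 2 else 0.0
    return BatchMetrics(
        ssim_values=ssims, psnr_values=psnrs,
        ssim_mean=float(np.mean(ssims)), ssim_sd=ssim_sd,
        psnr_mean=float(np.mean(psnrs)), psnr_sd=psnr_sd,
        n=n, sd_degenerate=degenerate,
    )
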