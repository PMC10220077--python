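"""Direction-condition evaluation harness.

Models are scored on a held-out test set under named conditions —
``with_artefacts`` (the uncorrected baseline), ``consistent`` /
``inconsistent`` (test ghosting direction matches / opposes the training
direction) and ``both_directions`` — with global SSIM and PSNR per image,
paired two-tailed t-tests between conditions (significance at p < 0.005),
and percentage improvement rates over the uncorrected baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import denormalize_output, normalize_input
from .metrics import SSIMConstants, batch_metrics
from .types import ImageGrid, LeakageError, PairedSample, ShapeError

__all__ = [
    "QualityReport",
    "ComparisonResult",
    "evaluate_condition",
    "paired_t_test",
    "improvement_rate",
    "build_comparison_table",
    "plot_metric_boxplots",
]

CONDITIONS = ("with_artefacts", "consistent", "inconsistent", "both_directions")

#: p-value threshold used throughout for significance flags.
P_THRESHOLD = 0.005


@dataclass
class QualityReport:
    condition: str
    model_kind: str
    per_image_ssim: list[float]
    per_image_psnr: list[float]
    ssim_mean: float
    ssim_sd: float
    psnr_mean: float
    psnr_sd: float
    n: int

    def summary(self) -> str:
        return (f"{self.model_kind}/{self.condition}: "
                f"SSIM {self.ssim_mean:.3f}±{self.ssim_sd:.3f}, "
                f"PSNR {self.psnr_mean:.2f}±{self.psnr_sd:.2f} dB (n={self.n})")


@dataclass
class ComparisonResult:
    baseline_condition: str
    comparison_condition: str
    metric: str
    t_statistic: float
    p_value: float
    significant: bool
    degenerate: bool = False  # all per-image differences identical


def _check_leakage(test_samples: list[PairedSample],
                   train_keys: set[tuple[str, int]] | None) -> None:
    if train_keys is None:
        return
    overlap = {s.key for s in test_samples} & train_keys
    if overlap:
        raise LeakageError(
            f"{len(overlap)} test samples appear in the training manifest: "
            f"{sorted(overlap)[:3]}..."
        )


def evaluate_condition(model, test_samples: list[PairedSample], condition: str,
                       train_keys: set[tuple[str, int]] | None = None,
                       constants: SSIMConstants | None = None,
                       ssim_mode: str = "paper_global",
                       psnr_peak: float | None = 255.0) -> QualityReport:
    """Score corrected (or raw corrupted) images against their clean pairs.

    ``model`` is a TrainedModel, or None for the ``with_artefacts``
    baseline.  Candidate and reference are both brought to the [0, 255]
    output scale before the metrics, so PSNR defaults to the shared
    dynamic-range peak of 255 (pass ``psnr_peak=None`` for the per-image
    peak form).  If ``train_keys`` is given, test samples overlapping the
    training set raise :class:`LeakageError`.
    """
    if not test_samples:
        raise ValueError("evaluate_condition requires at least one test sample")
    _check_leakage(test_samples, train_keys)
    from .models import correct_image  # local import to avoid a cycle

    pairs = []
    for s in test_samples:
        reference = denormalize_output(normalize_input(s.clean))
        corrupted_norm = normalize_input(s.corrupted)
        if model is None:
            candidate = denormalize_output(corrupted_norm)
        else:
            candidate = correct_image(model, corrupted_norm)
        pairs.append((candidate, reference))
    bm = batch_metrics(pairs, constants=constants, mode=ssim_mode, peak=psnr_peak)
    return QualityReport(
        condition=condition,
        model_kind=getattr(model, "kind", "none"),
        per_image_ssim=bm.ssim_values, per_image_psnr=bm.psnr_values,
        ssim_mean=bm.ssim_mean, ssim_sd=bm.ssim_sd,
        psnr_mean=bm.psnr_mean, psnr_sd=bm.psnr_sd, n=bm.n,
    )


def paired_t_test(a: list[float], b: list[float], metric: str = "",
                  baseline_condition: str = "", comparison_condition: str = "",
                  ) -> ComparisonResult:
    """Two-tailed paired t-test on per-image metric differences.

    The same test images underlie every condition, so the paired form is
    appropriate.  Zero-variance differences are flagged degenerate
    (t = 0, p = 1 when the means agree; t = ±inf, p = 0 otherwise).
    """
    a_arr, b_arr = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a_arr.shape != b_arr.shape:
        raise ShapeError("paired_t_test requires equally long metric lists")
    if a_arr.size < 2:
        raise ValueError("paired_t_test requires n >= 2")
    d = a_arr - b_arr
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = float(np.sign(d.mean()) * np.inf), 0.0
        return ComparisonResult(baseline_condition, comparison_condition, metric,
                                t, p, p < P_THRESHOLD, degenerate=True)
    res = stats.ttest_rel(a_arr, b_arr)
    t, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(baseline_condition, comparison_condition, metric,
                            t, p, p < P_THRESHOLD)


def improvement_rate(corrected: QualityReport, baseline: QualityReport,
                     metric: str = "ssim") -> float:
    """Percent change of the mean metric relative to the baseline mean."""
    if corrected.n != baseline.n:
        raise ValueError("reports must come from the same test set")
    attr = {"ssim": "ssim_mean", "psnr": "psnr_mean"}[metric]
    base = getattr(baseline, attr)
    if base == 0:
        raise ZeroDivisionError("baseline mean is zero")
    return 100.0 * (getattr(corrected, attr) - base) / base


def build_comparison_table(reports: list[QualityReport], metric: str = "ssim",
                           reference_condition: str = "consistent",
                           ) -> pd.DataFrame:
    """Render mean ± SD cells (rows = model kinds, columns = conditions).

    Cells for conditions differing significantly (paired t-test, p < 0.005)
    from the same model's reference condition are starred.  Missing
    condition cells are left as an em-dash gap.
    """
    attr_mean = {"ssim": "ssim_mean", "psnr": "psnr_mean"}[metric]
    attr_sd = {"ssim": "ssim_sd", "psnr": "psnr_sd"}[metric]
    attr_list = {"ssim": "per_image_ssim", "psnr": "per_image_psnr"}[metric]
    models = sorted({r.model_kind for r in reports if r.model_kind != "none"})
    conditions = [c for c in CONDITIONS
                  if any(r.condition == c for r in reports)]
    by_key = {(r.model_kind, r.condition): r for r in reports}
    fmt = "{:.3f}" if metric == "ssim" else "{:.2f}"
    rows = {}
    baseline = next((r for r in reports if r.condition == "with_artefacts"), None)
    if baseline is not None:
        rows["w/ artefacts"] = {
            c: (fmt.format(baseline.ssim_mean if metric == "ssim" else baseline.psnr_mean)
                + " ± " + fmt.format(getattr(baseline, attr_sd))
                if c == "with_artefacts" else "—")
            for c in conditions
        }
    for m in models:
        row = {}
        ref = by_key.get((m, reference_condition))
        for c in conditions:
            r = by_key.get((m, c))
            if r is None or c == "with_artefacts":
                row[c] = "—"
                continue
            cell = fmt.format(getattr(r, attr_mean)) + " ± " + fmt.format(getattr(r, attr_sd))
            if ref is not None and c != reference_condition and r.n == ref.n:
                cmp = paired_t_test(getattr(r, attr_list), getattr(ref, attr_list),
                                    metric=metric)
                if cmp.significant:
                    cell += "*"
            row[c] = cell
        rows[m] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=conditions)


def plot_metric_boxplots(reports: list[QualityReport], metric: str,
                         path: str | Path) -> Path:
    """Per-condition box plots of the per-image metric values (optional PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    attr = {"ssim": "per_image_ssim", "psnr": "per_image_psnr"}[metric]
    labels = [f"{r.model_kind}\n{r.condition}" for r in reports]
    data = [getattr(r, attr) for r in reports]
    fig, ax = plt.subplots(figsize=(1.6 * len(reports) + 2, 4))
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel(metric.upper())
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
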