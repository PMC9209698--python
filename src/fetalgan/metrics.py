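"""Segmentation overlap metrics: Dice, Jaccard, precision, sensitivity, specificity."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume_io import BinaryMask

__all__ = ["SegmentationMetrics", "compute_metrics", "summarize", "METRIC_NAMES"]

METRIC_NAMES = ("dice", "jaccard", "precision", "sensitivity", "specificity")


@dataclass
class SegmentationMetrics:
    """The five overlap statistics and voxel confusion counts for one scan."""

    dice: float
    jaccard: float
    precision: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    fn: int
    tn: int
    id: str = ""

    def as_dict(self) -> dict:
        d = {"id": self.id}
        d.update({k: getattr(self, k) for k in METRIC_NAMES})
        d.update({k: getattr(self, k) for k in ("tp", "fp", "fn", "tn")})
        return d


def compute_metrics(pred: BinaryMask | np.ndarray, truth: BinaryMask | np.ndarray,
                    id: str = "") -> SegmentationMetrics:
    """Voxel-confusion metrics of a predicted mask against the ground truth.

    dice = 2TP/(2TP+FP+FN); jaccard = TP/(TP+FP+FN); precision = TP/(TP+FP);
    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP).  Zero-denominator
    conventions: precision := 0 when no voxel is predicted foreground;
    specificity := 1 when there is no true-or-false-positive background
    evidence (TN+FP = 0).
    """
    p = pred.values if isinstance(pred, BinaryMask) else np.asarray(pred, dtype=bool)
    t = truth.values if isinstance(truth, BinaryMask) else np.asarray(truth, dtype=bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    if not t.any():
        raise ValueError("ground-truth mask is empty")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    dice = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    jaccard = tp / (tp + fp + fn) if (tp + fp + fn) else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    sensitivity = tp / (tp + fn)  # truth non-empty, so tp + fn >= 1
    specificity = tn / (tn + fp) if (tn + fp) else 1.0
    if not id and isinstance(pred, BinaryMask):
        id = pred.id
    return SegmentationMetrics(dice, jaccard, precision, sensitivity, specificity,
                               tp, fp, fn, tn, id=id)


def summarize(rows: list[SegmentationMetrics]) -> pd.DataFrame:
    """Per-metric mean and sample standard deviation (n-1 denominator).

    A single row reports SD 0 by convention, with n = 1 recorded so the
    degenerate case is visible in the table.
    """
    if len(rows) == 0:
        raise ValueError("summarize requires at least one metrics row")
    table = pd.DataFrame([r.as_dict() for r in rows])
    out = []
    for name in METRIC_NAMES:
        vals = table[name].to_numpy(dtype=float)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        out.append({"metric": name, "mean": float(vals.mean()), "sd": sd, "n": len(vals)})
    return pd.DataFrame(out)


def metrics_table(rows: list[SegmentationMetrics]) -> pd.DataFrame:
    """Long-format per-scan table (one row per scan)."""
    return pd.DataFrame([r.as_dict() for r in rows])
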