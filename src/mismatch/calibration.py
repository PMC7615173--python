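"""Pixel-wise calibration analysis and segmentation accuracy metrics.

For binary segmentation each pixel's predicted class is the more probable
of foreground (probability ``p``) and background (``1-p``), so its
confidence ``max(p, 1-p)`` lies in [0.5, 1].  Pixels are assigned to M
equal-width confidence bins over [0.5, 1] (default M=5); per-bin accuracy
is the fraction of correctly classified pixels and per-bin confidence the
mean confidence.  The expected calibration error (ECE) is the
count-weighted mean absolute accuracy-confidence gap:

    ECE = sum_m (|B_m| / n) * |acc(B_m) - conf(B_m)|

Bins are left-open/right-closed except the first; a confidence exactly on
an interior edge falls in the lower bin.  Empty bins contribute zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["CalibrationReport", "bin_pixels", "reliability_diagram_data",
           "segmentation_metrics", "iou_ece_trend"]


@dataclass
class CalibrationReport:
    bin_edges: np.ndarray        # M+1 edges over [0.5, 1]
    counts: np.ndarray           # |B_m|
    accuracy: np.ndarray         # acc(B_m); nan for empty bins
    confidence: np.ndarray       # conf(B_m); nan for empty bins
    ece: float
    n_pixels: int

    def to_frame(self) -> pd.DataFrame:
        return reliability_diagram_data(self)


def bin_pixels(p: np.ndarray, y: np.ndarray, M: int = 5) -> CalibrationReport:
    """Calibration report for probability map ``p`` against binary mask ``y``.

    A probability of exactly 0.5 is classed as foreground (argmax tie goes
    to the positive class).
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    if p.size == 0:
        raise ValueError("empty input")
    if M < 1:
        raise ValueError("M must be >= 1")
    p = p.ravel()
    y = y.ravel().astype(bool)
    pred = p >= 0.5
    conf = np.maximum(p, 1.0 - p)
    correct = pred == y

    edges = np.linspace(0.5, 1.0, M + 1)
    # interior edge ties -> lower bin; clamp 0.5 into the first bin
    idx = np.clip(np.searchsorted(edges, conf, side="left") - 1, 0, M - 1)
    counts = np.bincount(idx, minlength=M)
    acc_sum = np.bincount(idx, weights=correct.astype(float), minlength=M)
    conf_sum = np.bincount(idx, weights=conf, minlength=M)
    with np.errstate(invalid="ignore"):
        accuracy = np.where(counts > 0, acc_sum / np.maximum(counts, 1), np.nan)
        confidence = np.where(counts > 0, conf_sum / np.maximum(counts, 1), np.nan)
    occupied = counts > 0
    ece = float(np.sum(counts[occupied] / p.size
                       * np.abs(accuracy[occupied] - confidence[occupied])))
    return CalibrationReport(bin_edges=edges, counts=counts, accuracy=accuracy,
                             confidence=confidence, ece=ece, n_pixels=p.size)


def reliability_diagram_data(report: CalibrationReport) -> pd.DataFrame:
    """Per-bin (midpoint, count, accuracy, confidence) table for bar plots."""
    mids = 0.5 * (report.bin_edges[:-1] + report.bin_edges[1:])
    return pd.DataFrame({
        "bin_low": report.bin_edges[:-1],
        "bin_high": report.bin_edges[1:],
        "bin_mid": mids,
        "count": report.counts,
        "accuracy": report.accuracy,
        "confidence": report.confidence,
        "empty": report.counts == 0,
    })


def _surface(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask, iterations=1, border_value=0)
    return mask & ~eroded


def segmentation_metrics(pred_mask: np.ndarray, y: np.ndarray,
                         spacing=None) -> dict[str, float]:
    """IoU, Dice, Hausdorff distance and average surface distance.

    Distances are computed on surface voxels, scaled by ``spacing``
    (defaults to unit voxels).  Two empty masks are treated as a perfect
    match; one empty mask yields infinite distances with a warning.
    """
    a = np.asarray(pred_mask).astype(bool)
    b = np.asarray(y).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    spacing = np.ones(a.ndim) if spacing is None else np.asarray(spacing, dtype=float)

    inter = np.count_nonzero(a & b)
    union = np.count_nonzero(a | b)
    size = np.count_nonzero(a) + np.count_nonzero(b)
    if union == 0:
        return {"iou": 1.0, "dice": 1.0, "hausdorff": 0.0, "asd": 0.0}
    iou = inter / union
    dice = 2.0 * inter / size
    if not a.any() or not b.any():
        warnings.warn("one mask is empty: surface distances are infinite")
        return {"iou": iou, "dice": dice, "hausdorff": np.inf, "asd": np.inf}

    sa, sb = _surface(a), _surface(b)
    dist_to_b = ndimage.distance_transform_edt(~sb, sampling=spacing)
    dist_to_a = ndimage.distance_transform_edt(~sa, sampling=spacing)
    d_ab = dist_to_b[sa]
    d_ba = dist_to_a[sb]
    hausdorff = float(max(d_ab.max(), d_ba.max()))
    asd = float(np.concatenate([d_ab, d_ba]).mean())
    return {"iou": iou, "dice": dice, "hausdorff": hausdorff, "asd": asd}


def iou_ece_trend(ious, eces) -> dict[str, float]:
    """Quadratic trend of per-image IoU as a function of per-image ECE.

    Fits ``iou = a*ece^2 + b*ece + c`` and reports the magnitude of the
    fitted slope at the mean observed ECE; a flatter trend means accuracy
    degrades less as calibration worsens.
    """
    ious = np.asarray(ious, dtype=float)
    eces = np.asarray(eces, dtype=float)
    if ious.shape != eces.shape or ious.size < 3:
        raise ValueError("need >= 3 paired (iou, ece) points")
    a, b, c = np.polyfit(eces, ious, deg=2)
    slope = 2.0 * a * eces.mean() + b
    return {"a": float(a), "b": float(b), "c": float(c),
            "slope_at_mean_ece": float(slope),
            "slope_magnitude": float(abs(slope))}
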