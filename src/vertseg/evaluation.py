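"""Quantitative comparison of predicted and reference segmentations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import SegMask

__all__ = ["EvalReport", "dice", "mask_volume", "detection_error", "evaluate_masks"]


def dice(a: SegMask | np.ndarray, b: SegMask | np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) between binary masks.

    Two empty masks are defined as perfectly overlapping (DSC = 1.0).
    """
    pa = (a.pixels if isinstance(a, SegMask) else np.asarray(a)).astype(bool)
    pb = (b.pixels if isinstance(b, SegMask) else np.asarray(b)).astype(bool)
    if pa.shape != pb.shape:
        raise ValueError(f"mask shapes differ: {pa.shape} vs {pb.shape}")
    denom = int(pa.sum()) + int(pb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((pa & pb).sum()) / denom


def mask_volume(m: SegMask | np.ndarray, spacing: float, thickness: float) -> float:
    """Physical volume in mm³: foreground count · spacing² · thickness."""
    if spacing <= 0 or thickness <= 0:
        raise ValueError("spacing and thickness must be positive")
    px = (m.pixels if isinstance(m, SegMask) else np.asarray(m)).astype(bool)
    return float(px.sum()) * spacing * spacing * thickness


def detection_error(pred_centers, true_centers) -> float:
    """Mean Euclidean distance between matched center lists.

    Lists are matched by vertical order (the stacking invariant makes
    assignment trivial); they must have equal length — unmatched bodies are
    detection failures and are counted separately by the caller.
    """
    pred = np.asarray(pred_centers, dtype=float)
    true = np.asarray(true_centers, dtype=float)
    if pred.size == 0 or true.size == 0:
        raise ValueError("center lists must be non-empty")
    if pred.shape != true.shape:
        raise ValueError("center lists must be matched (equal length)")
    pred = pred[np.argsort(pred[:, 0], kind="stable")]
    true = true[np.argsort(true[:, 0], kind="stable")]
    return float(np.mean(np.hypot(pred[:, 0] - true[:, 0], pred[:, 1] - true[:, 1])))


@dataclass
class EvalReport:
    """Per-vertebra and aggregate comparison of predicted vs reference masks."""

    dsc: list[float]
    voxels_pred: list[int]
    voxels_ref: list[int]
    volume_pred_mm3: list[float]
    volume_ref_mm3: list[float]
    detection_error_px: float | None = None

    @property
    def dsc_mean(self) -> float:
        return float(np.mean(self.dsc))

    @property
    def dsc_sd(self) -> float:
        return float(np.std(self.dsc, ddof=1)) if len(self.dsc) > 1 else 0.0

    def to_json(self) -> dict:
        return {
            "per_vertebra": [
                {
                    "label": i + 1,
                    "dsc": self.dsc[i],
                    "voxels_pred": self.voxels_pred[i],
                    "voxels_ref": self.voxels_ref[i],
                    "volume_pred_mm3": self.volume_pred_mm3[i],
                    "volume_ref_mm3": self.volume_ref_mm3[i],
                }
                for i in range(len(self.dsc))
            ],
            "dsc_mean": self.dsc_mean,
            "dsc_sd": self.dsc_sd,
            "detection_error_px": self.detection_error_px,
        }


def evaluate_masks(
    predicted: list[SegMask],
    reference: list[SegMask],
    spacing: float = 0.39,
    thickness: float = 3.0,
    pred_centers=None,
    true_centers=None,
) -> EvalReport:
    """Build an evaluation report for matched mask lists (by vertical rank)."""
    if len(predicted) != len(reference):
        raise ValueError("predicted and reference mask counts differ")
    report = EvalReport(
        dsc=[dice(p, r) for p, r in zip(predicted, reference)],
        voxels_pred=[m.count() for m in predicted],
        voxels_ref=[m.count() for m in reference],
        volume_pred_mm3=[mask_volume(m, spacing, thickness) for m in predicted],
        volume_ref_mm3=[mask_volume(m, spacing, thickness) for m in reference],
    )
    if pred_centers is not None and true_centers is not None:
        report.detection_error_px = detection_error(pred_centers, true_centers)
    return report
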