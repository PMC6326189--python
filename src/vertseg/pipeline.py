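"""End-to-end pipeline: one user ROI in, all vertebra masks out."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .core_io import BoundaryContour, Image2D, RoiBox, SegMask
from .evaluation import EvalReport, evaluate_masks
from .roi_detection import DetectionResult, detect
from .roi_refinement import refine_roi
from .segmentation import segment_vertebra

__all__ = ["PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything one pipeline run produced."""

    detection: DetectionResult
    refined_rois: list[RoiBox]
    masks: list[SegMask]
    contours: list[BoundaryContour]
    failures: list[dict] = field(default_factory=list)
    report: EvalReport | None = None
    config: PipelineConfig = field(default_factory=PipelineConfig)

    def to_json(self) -> dict:
        out = {
            "config": self.config.to_dict(),
            "detection": self.detection.to_json(),
            "refined_rois": [r.to_json() for r in self.refined_rois],
            "n_masks": len(self.masks),
            "failures": self.failures,
        }
        if self.report is not None:
            out["evaluation"] = self.report.to_json()
        return out


def run_pipeline(
    image: Image2D,
    user_roi: RoiBox,
    config: PipelineConfig | None = None,
    reference_masks: list[SegMask] | None = None,
    true_centers=None,
) -> PipelineResult:
    """Detect, refine and segment every vertebral body from one user ROI.

    Per-vertebra failures are recorded (with the vertebra index) rather than
    aborting the run; partial results are still returned. When reference
    masks are supplied an evaluation report is attached.
    """
    cfg = config or PipelineConfig()
    detection = detect(
        image,
        user_roi,
        max_bodies=cfg.max_bodies,
        beta=cfg.beta,
        disc_refine=cfg.disc_refine,
    )

    refined: list[RoiBox] = []
    masks: list[SegMask] = []
    contours: list[BoundaryContour] = []
    failures: list[dict] = []
    for i, center in enumerate(detection.vb_centers):
        roi = RoiBox(center=center, lx=user_roi.lx, ly=user_roi.ly)
        try:
            roi = refine_roi(
                image,
                roi,
                alpha=cfg.alpha,
                step_frac=cfg.step_frac,
                max_extend=cfg.max_extend,
                canny_sigma=cfg.canny_sigma,
            )
            mask, contour = segment_vertebra(
                image,
                roi,
                spacing_frac=cfg.spacing_frac,
                k_clusters=cfg.k_clusters,
                delta=cfg.delta,
                canny_sigma=cfg.canny_sigma,
                seed=cfg.seed,
            )
        except Exception as exc:  # noqa: BLE001 - reported per vertebra
            logger.warning("vertebra %d failed: %s", i + 1, exc)
            failures.append({"vertebra": i + 1, "error": str(exc)})
            continue
        refined.append(roi)
        masks.append(SegMask(mask.pixels, label=i + 1))
        contours.append(contour)

    report = None
    if reference_masks is not None and len(reference_masks) == len(masks):
        report = evaluate_masks(
            masks,
            reference_masks,
            spacing=image.pixel_spacing,
            thickness=image.slice_thickness,
            pred_centers=detection.vb_centers if true_centers is not None else None,
            true_centers=true_centers,
        )
    return PipelineResult(
        detection=detection,
        refined_rois=refined,
        masks=masks,
        contours=contours,
        failures=failures,
        report=report,
        config=cfg,
    )
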