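"""Per-ROI fine tuning: orientation and boundary adjustment.

Adjacent vertebral bodies rotate slightly against each other (kyphosis /
lordosis), and a fixed-size ROI propagated by correlation may clip a body.
This stage fixes both per ROI:

1. **Orientation** — Canny edges of the ROI crop are Hough-transformed; for
   a rectangle-like object the number of occupied distance bins ("length of
   the nonzero area") at a candidate angle is minimal when the angle matches
   the object's axis, so the argmin over angles estimates the body rotation
   and the ROI is counter-rotated.
2. **Extent** — edge counts are projected per column (``Px``) and per row
   (``Py``). A body side lying inside the ROI produces a projection peak
   well above the central value; a side whose peak is missing means the body
   is clipped on that side, and the ROI is grown outward step by step until
   all four peaks appear.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import feature, transform

from .core_io import Image2D, RoiBox, _rotation_matrix

__all__ = [
    "EdgeMap",
    "HoughImage",
    "ProjectionProfiles",
    "InsufficientEdgesError",
    "detect_edges",
    "hough_orientation_image",
    "estimate_rotation",
    "derotate_roi",
    "project_edges",
    "adjust_boundaries",
    "refine_roi",
]

logger = logging.getLogger(__name__)


class InsufficientEdgesError(RuntimeError):
    """Too few edge pixels to estimate an orientation."""


@dataclass(frozen=True)
class EdgeMap:
    """Binary edge raster over an ROI crop."""

    pixels: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "pixels", np.asarray(self.pixels).astype(np.uint8))

    @property
    def n_edges(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class HoughImage:
    """Hough accumulator: rows index distance rho, columns index angle theta."""

    H: np.ndarray
    thetas_deg: np.ndarray
    rhos: np.ndarray

    def nonzero_extent(self) -> np.ndarray:
        """Number of occupied rho bins per angle (Fig.-style 'nonzero length')."""
        return np.count_nonzero(self.H > 0, axis=0)


@dataclass(frozen=True)
class ProjectionProfiles:
    """Edge counts projected on the x-axis (per column) and y-axis (per row)."""

    Px: np.ndarray
    Py: np.ndarray

    @classmethod
    def from_edges(cls, edges: EdgeMap) -> "ProjectionProfiles":
        e = edges.pixels
        return cls(Px=e.sum(axis=0).astype(int), Py=e.sum(axis=1).astype(int))


def detect_edges(
    roi_pixels: np.ndarray,
    sigma: float = 1.4,
    low_quantile: float = 0.70,
    high_quantile: float = 0.90,
) -> EdgeMap:
    """Canny edge map of an ROI crop.

    Hysteresis thresholds are gradient-magnitude quantiles, which keeps the
    rule invariant to intensity scale. A constant patch yields an empty map.
    """
    patch = np.asarray(roi_pixels, dtype=float)
    if min(patch.shape) < 16:
        raise ValueError(f"ROI patch must be at least 16x16, got {patch.shape}")
    if np.ptp(patch) == 0:
        return EdgeMap(np.zeros(patch.shape, dtype=np.uint8))
    e = feature.canny(
        patch,
        sigma=sigma,
        low_threshold=low_quantile,
        high_threshold=high_quantile,
        use_quantiles=True,
    )
    return EdgeMap(e)


def hough_orientation_image(edges: EdgeMap, step: float = 1.0) -> HoughImage:
    """Line-Hough accumulator of an edge map over the half-circle of angles."""
    thetas_deg = np.arange(-90.0, 90.0, step)
    H, angles, rhos = transform.hough_line(
        edges.pixels.astype(bool), theta=np.deg2rad(thetas_deg)
    )
    return HoughImage(H=H, thetas_deg=thetas_deg, rhos=rhos)


def estimate_rotation(edges: EdgeMap, step: float = 1.0, min_edges: int = 20) -> float:
    """Rotation of a rectangle-like edge set, degrees CCW in display space.

    The occupied-bin count of the Hough accumulator at angle theta measures
    the extent of the edge set projected at that angle; for a rectangle it
    is minimal when theta aligns with one of the rectangle's axes. The
    estimate is therefore 90-degree periodic: the argmin over the full
    half-circle maps back to a rotation in (-45, 45]. Tied minima (a flat
    valley) resolve to their median angle.
    """
    if edges.n_edges < min_edges:
        raise InsufficientEdgesError(
            f"insufficient edges for rotation estimate ({edges.n_edges} < {min_edges})"
        )
    hough = hough_orientation_image(edges, step=step)
    extent = hough.nonzero_extent().astype(float)
    candidates = hough.thetas_deg[extent == extent.min()]
    # content rotated by +phi (CCW display) moves the tightest projection to
    # theta = -phi (mod 90); map candidates to the principal interval FIRST
    # so that tied minima on both rectangle axes agree before the median.
    phis = (-candidates + 45.0) % 90.0 - 45.0
    return float(np.median(phis))


def dominant_component(edges: EdgeMap) -> EdgeMap:
    """Keep only the largest 8-connected edge component.

    In an ROI crop the vertebral-body rim forms the longest connected edge
    curve; discs and neighbouring structures contribute smaller separate
    components that would otherwise bias the orientation estimate.
    """
    lab, n = ndimage.label(edges.pixels, structure=np.ones((3, 3), dtype=int))
    if n <= 1:
        return edges
    sizes = ndimage.sum(edges.pixels, lab, index=range(1, n + 1))
    return EdgeMap(lab == (1 + int(np.argmax(sizes))))


def derotate_roi(roi: RoiBox, angle: float) -> RoiBox:
    """Counter-rotate an ROI so its re-extracted crop is axis-aligned.

    ``angle`` is the rotation estimated on the crop extracted at the ROI's
    current angle; the returned box extracts an upright view of the body.
    """
    if abs(angle) > 45:
        raise ValueError("derotation restricted to |angle| <= 45 degrees")
    new = roi.angle + angle
    if new > 90.0:
        new -= 180.0
    elif new <= -90.0:
        new += 180.0
    return roi.with_angle(new)


def project_edges(edges: EdgeMap) -> ProjectionProfiles:
    return ProjectionProfiles.from_edges(edges)


def _side_present(profile: np.ndarray, side: str, alpha: float) -> bool:
    """Does the projection profile show a body edge on this half?

    Three pixels at the crop border are excluded: a projection peak hugging
    the border is the mid-line of a cortical rim whose outer half (and blur)
    still continues outside the ROI. The interior peak must also dominate
    any border peak — otherwise the side's real edge sits at (or beyond)
    the border and the ROI must grow.
    """
    n = len(profile)
    c = n // 2
    if side == "low":
        interval, whole = profile[3:c], profile[:c]
    else:
        interval, whole = profile[c + 1 : n - 3], profile[c + 1 :]
    if interval.size == 0:
        return False
    return (
        float(interval.max()) >= alpha * float(profile[c])
        and float(interval.max()) >= 0.5 * float(whole.max())
    )


def _max_outward(roi: RoiBox, side: str, shape: tuple[int, int]) -> float:
    """Largest outward extension of one box side that stays inside the image."""
    rot = _rotation_matrix(roi.angle)
    out_local = {
        "left": np.array([0.0, -1.0]),
        "right": np.array([0.0, 1.0]),
        "up": np.array([-1.0, 0.0]),
        "down": np.array([1.0, 0.0]),
    }[side]
    u = rot @ out_local
    corners = roi.corners()
    idx = {"left": (0, 3), "right": (1, 2), "up": (0, 1), "down": (2, 3)}[side]
    t_max = math.inf
    for i in idx:
        p = corners[i]
        for k, bound in ((0, shape[0] - 1), (1, shape[1] - 1)):
            if u[k] > 1e-12:
                t_max = min(t_max, (bound - p[k]) / u[k])
            elif u[k] < -1e-12:
                t_max = min(t_max, (0 - p[k]) / u[k])
    return max(0.0, t_max)


def _grow(roi: RoiBox, side: str, amount: int) -> RoiBox:
    """Extend one side of the box outward by ``amount`` pixels."""
    rot = _rotation_matrix(roi.angle)
    half = amount / 2.0
    shift_local = {
        "left": np.array([0.0, -half]),
        "right": np.array([0.0, half]),
        "up": np.array([-half, 0.0]),
        "down": np.array([half, 0.0]),
    }[side]
    dr, dc = rot @ shift_local
    lx = roi.lx + (amount if side in ("left", "right") else 0)
    ly = roi.ly + (amount if side in ("up", "down") else 0)
    return replace(roi, center=(roi.center[0] + dr, roi.center[1] + dc), lx=lx, ly=ly)


def adjust_boundaries(
    image: Image2D,
    roi: RoiBox,
    alpha: float = 3.0,
    step_frac: float = 0.1,
    max_extend: float = 0.5,
    canny_sigma: float = 1.4,
    max_iter: int = 20,
) -> RoiBox:
    """Grow the ROI until all four vertebral-body edges project inside it.

    For each side the projection maximum over the corresponding half-profile
    must exceed ``alpha`` times the central value; failing sides extend
    outward by ``ceil(step_frac * side_length)`` px, re-testing on the
    re-extracted crop, up to ``max_extend`` of the original side length per
    side. Extension beyond the image is clamped with a warning.
    """
    if alpha <= 1:
        raise ValueError("alpha must exceed 1")
    lx0, ly0 = roi.lx, roi.ly
    budget = {s: max_extend * (lx0 if s in ("left", "right") else ly0)
              for s in ("left", "right", "up", "down")}
    step = {s: max(1, math.ceil(step_frac * (lx0 if s in ("left", "right") else ly0)))
            for s in ("left", "right", "up", "down")}
    for _ in range(max_iter):
        crop = roi.extract(image)
        prof = ProjectionProfiles.from_edges(detect_edges(crop, sigma=canny_sigma))
        failing = []
        if not _side_present(prof.Px, "low", alpha):
            failing.append("left")
        if not _side_present(prof.Px, "high", alpha):
            failing.append("right")
        if not _side_present(prof.Py, "low", alpha):
            failing.append("up")
        if not _side_present(prof.Py, "high", alpha):
            failing.append("down")
        grew = False
        for side in failing:
            amount = min(step[side], int(budget[side]))
            if amount <= 0:
                continue
            allowed = int(_max_outward(roi, side, image.shape))
            if allowed < amount:
                if allowed <= 0:
                    logger.warning("ROI %s extension clamped at image bound", side)
                    budget[side] = 0
                    continue
                logger.warning("ROI %s extension clamped to %d px at image bound", side, allowed)
                amount = allowed
            roi = _grow(roi, side, amount)
            budget[side] -= amount
            grew = True
        if not grew:
            break
    return roi


def refine_roi(
    image: Image2D,
    roi: RoiBox,
    alpha: float = 3.0,
    step_frac: float = 0.1,
    max_extend: float = 0.5,
    canny_sigma: float = 1.4,
    rotation_passes: int = 2,
    rot_margin: float = 1.4,
) -> RoiBox:
    """Full per-ROI refinement: de-rotate, then adjust boundaries.

    Rotation is estimated on an analysis window enlarged by ``rot_margin``
    (so a tilted body is never clipped), reduced to its dominant edge
    component; up to ``rotation_passes`` passes remove residual rotation.
    Boundary adjustment then runs on the axis-aligned crop. ROIs whose crops
    carry too few edges keep their angle.
    """
    for _ in range(rotation_passes):
        analysis = RoiBox(
            center=roi.center,
            lx=int(round(roi.lx * rot_margin)),
            ly=int(round(roi.ly * rot_margin)),
            angle=roi.angle,
        )
        crop = analysis.extract(image, mode="nearest")
        try:
            edges = dominant_component(detect_edges(crop, sigma=canny_sigma))
            angle = estimate_rotation(edges)
        except InsufficientEdgesError:
            logger.warning("too few edges at %s; keeping ROI angle", roi.center)
            break
        if abs(angle) < 1.0:
            break
        roi = derotate_roi(roi, angle)
    return adjust_boundaries(
        image,
        roi,
        alpha=alpha,
        step_frac=step_frac,
        max_extend=max_extend,
        canny_sigma=canny_sigma,
    )
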