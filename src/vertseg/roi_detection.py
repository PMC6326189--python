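"""Vertebral-body localisation from a single user ROI.

One user-drawn box around any one vertebral body is matched against the
whole image by zero-mean normalised cross-correlation (ZNCC). The global
correlation peak recovers the user's body; after suppressing its
neighbourhood, the next peak gives the adjacent body and the two together
define a reference distance ``d`` along the stacking axis. Further bodies
are found by stepping ``d`` along that axis and taking the best peak inside
an ROI-sized search window, alternating upward and downward until the peak
falls below threshold or the window leaves the image. Horizontal positions
are then cross-checked against intervertebral-disc correlation peaks, which
localise more sharply than the bodies themselves.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core_io import Image2D, RoiBox, round_half_away

__all__ = [
    "CorrelationMap",
    "DetectionResult",
    "DetectionError",
    "SingleVertebraError",
    "DegenerateDistanceError",
    "compute_correlation_map",
    "find_vertebra_centers",
    "refine_with_discs",
    "detect",
]

logger = logging.getLogger(__name__)

_VAR_EPS = 1e-10  # window centered-norm below this counts as constant
_TIE_BAND = 0.10  # relative score band within which peaks count as rivals


class DetectionError(RuntimeError):
    """Vertebra detection failed."""


class SingleVertebraError(DetectionError):
    """Only one vertebra could be located ('single vertebra detected')."""


class DegenerateReferenceDistance(DetectionError):
    """The two strongest peaks are too close to define a reference distance."""


# Backwards-friendly alias matching the error wording used in reports.
DegenerateDistanceError = DegenerateReferenceDistance


@dataclass
class CorrelationMap:
    """Per-pixel template-match scores with a suppression mask.

    ``scores[p]`` is the ZNCC between the template and the equally sized
    patch centered at ``p``; suppressed pixels (image border where the patch
    exits, near-constant patches, and neighbourhoods of already-found peaks)
    are excluded from every argmax query.
    """

    scores: np.ndarray
    suppressed: np.ndarray

    def argmax(self, window: tuple[slice, slice] | None = None):
        """Best unsuppressed (row, col, score); ties break to smallest row, col."""
        sc = self.scores if window is None else self.scores[window]
        sup = self.suppressed if window is None else self.suppressed[window]
        if sup.size == 0 or sup.all():
            return None
        masked = np.where(sup, -2.0, sc)
        flat = int(np.argmax(masked))
        r, c = np.unravel_index(flat, masked.shape)
        if window is not None:
            r += window[0].start
            c += window[1].start
        return int(r), int(c), float(self.scores[r, c])

    def suppress_rect(self, center: tuple[int, int], half_h: int, half_w: int) -> None:
        r, c = center
        r0, r1 = max(0, r - half_h), min(self.scores.shape[0], r + half_h + 1)
        c0, c1 = max(0, c - half_w), min(self.scores.shape[1], c + half_w + 1)
        self.suppressed[r0:r1, c0:c1] = True


@dataclass
class DetectionResult:
    """Detected body and disc centers, ordered superior to inferior."""

    vb_centers: list[tuple[float, float]]
    disc_centers: list[tuple[float, float]]
    d: float
    user_index: int
    axis: tuple[float, float] = (1.0, 0.0)  # unit step direction, points inferior
    corrections: list[int] = None  # indices of bodies whose column was disc-corrected

    def __post_init__(self):
        if self.corrections is None:
            self.corrections = []

    def to_json(self) -> dict:
        return {
            "vb_centers": [list(p) for p in self.vb_centers],
            "disc_centers": [list(p) for p in self.disc_centers],
            "d": self.d,
            "user_index": self.user_index,
            "axis": list(self.axis),
            "corrections": list(self.corrections),
        }


def compute_correlation_map(image: Image2D | np.ndarray, template: np.ndarray) -> CorrelationMap:
    """Exact per-pixel ZNCC between ``template`` and every patch of ``image``.

    Computed with explicit per-window mean removal (numerically stable, no
    FFT round-off), block-wise so memory stays bounded. Border positions
    where the patch exits the image, and windows with (near-)zero variance,
    are marked suppressed.
    """
    img = image.pixels if isinstance(image, Image2D) else np.asarray(image, dtype=float)
    t = np.asarray(template, dtype=float)
    if t.ndim != 2:
        raise ValueError("template must be 2-D")
    th, tw = t.shape
    if th >= img.shape[0] or tw >= img.shape[1]:
        raise ValueError("template must be strictly smaller than the image")
    t0 = t - t.mean()
    tnorm = math.sqrt(float((t0 * t0).sum()))
    if tnorm <= _VAR_EPS:
        raise ValueError("constant template: correlation undefined")

    scores = np.zeros_like(img)
    suppressed = np.ones(img.shape, dtype=bool)
    windows = sliding_window_view(img, (th, tw))  # (Hout, Wout, th, tw)
    h_out, w_out = windows.shape[:2]
    # offset of patch center within the window (patch centered at p spans
    # rows [p-(th-1)//2, p+th//2])
    r_off, c_off = (th - 1) // 2, (tw - 1) // 2

    block = max(1, 8_000_000 // max(1, w_out * th * tw))
    for i0 in range(0, h_out, block):
        i1 = min(h_out, i0 + block)
        w = np.ascontiguousarray(windows[i0:i1], dtype=float)
        wc = w - w.mean(axis=(2, 3), keepdims=True)
        denom = np.sqrt((wc * wc).sum(axis=(2, 3))) * tnorm
        num = np.tensordot(wc, t0, axes=([2, 3], [0, 1]))
        ok = denom > _VAR_EPS * tnorm
        sc = np.zeros_like(num)
        np.divide(num, denom, out=sc, where=ok)
        np.clip(sc, -1.0, 1.0, out=sc)
        scores[i0 + r_off : i1 + r_off, c_off : c_off + w_out] = sc
        suppressed[i0 + r_off : i1 + r_off, c_off : c_off + w_out] = ~ok
    return CorrelationMap(scores=scores, suppressed=suppressed)


def _search_centers(
    cmap: CorrelationMap,
    lx: int,
    ly: int,
    beta: float,
    max_bodies: int,
) -> tuple[list[tuple[int, int]], float, np.ndarray, int]:
    """Shared peak-search procedure for vertebra and disc templates.

    Returns (centers sorted superior->inferior, d, unit axis, index of p1).
    """
    half_w = max(1, int(round(lx / 6.0)))  # lx/3-wide suppression rectangle
    half_h = max(1, int(round(ly / 6.0)))
    shape = cmap.scores.shape

    hit = cmap.argmax()
    if hit is None:
        raise DetectionError("correlation map fully suppressed")
    p1 = (hit[0], hit[1])
    s1 = hit[2]
    cmap.suppress_rect(p1, half_h, half_w)

    hit2 = cmap.argmax()
    if hit2 is None or hit2[2] < beta * s1:
        raise SingleVertebraError("single vertebra detected: no second correlation peak")
    # d is meant to be the *adjacent* body spacing, but the raw second argmax
    # can sit several pitches away when a farther body happens to match the
    # template slightly better. Among local maxima passing the same beta
    # acceptance used for all later peaks (and far enough from p1 to be a
    # distinct body), take the one nearest to p1.
    from scipy.ndimage import maximum_filter

    min_sep = max(lx, ly) / 2.0
    masked = np.where(cmap.suppressed, -2.0, cmap.scores)
    locmax = (
        (masked >= beta * max(s1, hit2[2]))
        & (masked == maximum_filter(masked, size=3))
        & ~cmap.suppressed
    )
    cand = np.argwhere(locmax)
    if cand.size:
        dist = np.hypot(cand[:, 0] - p1[0], cand[:, 1] - p1[1])
        ok = dist >= min_sep
        if ok.any():
            cand, dist = cand[ok], dist[ok]
            r2, c2 = cand[int(np.argmin(dist))]
            hit2 = (int(r2), int(c2), float(cmap.scores[r2, c2]))
    p2 = (hit2[0], hit2[1])
    s2 = hit2[2]
    d = math.dist(p1, p2)
    if d < min_sep:
        raise DegenerateReferenceDistance(
            f"degenerate reference distance d={d:.1f} < max(lx,ly)/2"
        )
    cmap.suppress_rect(p2, half_h, half_w)

    axis = np.array([p2[0] - p1[0], p2[1] - p1[1]], dtype=float) / d
    if axis[0] < 0:
        axis = -axis  # orient superior -> inferior
    threshold = beta * s2

    centers = [p1, p2]

    def window_at(expected: np.ndarray):
        er, ec = round_half_away(expected[0])[()], round_half_away(expected[1])[()]
        r0, r1 = er - ly // 2, er + ly // 2 + 1
        c0, c1 = ec - lx // 2, ec + lx // 2 + 1
        rr = slice(max(0, r0), min(shape[0], r1))
        cc = slice(max(0, c0), min(shape[1], c1))
        full = (r1 - r0) * (c1 - c0)
        clipped = max(0, rr.stop - rr.start) * max(0, cc.stop - cc.start)
        inside = 0 <= er < shape[0] and 0 <= ec < shape[1]
        return (rr, cc) if inside and clipped >= 0.25 * full else None

    for direction in (-1.0, 1.0):  # upward then downward along the axis
        anchor = np.array(min(centers) if direction < 0 else max(centers), dtype=float)
        while len(centers) < max_bodies:
            expected = anchor + direction * d * axis
            win = window_at(expected)
            if win is None:
                break
            hit = cmap.argmax(window=win)
            if hit is None or hit[2] < threshold:
                break
            p = (hit[0], hit[1])
            cmap.suppress_rect(p, half_h, half_w)
            centers.append(p)
            anchor = np.array(p, dtype=float)

    centers.sort()
    return centers, d, axis, centers.index(p1)


def find_vertebra_centers(
    cmap: CorrelationMap,
    roi: RoiBox,
    max_bodies: int = 8,
    beta: float = 0.6,
) -> DetectionResult:
    """Locate all vertebral-body centers from a correlation map.

    ``beta`` is the acceptance ratio: a window peak is kept only if its score
    is at least ``beta`` times the second peak's score (and the second peak
    itself must reach ``beta`` times the first's).
    """
    centers, d, axis, user_idx = _search_centers(cmap, roi.lx, roi.ly, beta, max_bodies)
    return DetectionResult(
        vb_centers=[(float(r), float(c)) for r, c in centers],
        disc_centers=[],
        d=d,
        user_index=user_idx,
        axis=(float(axis[0]), float(axis[1])),
    )


def refine_with_discs(
    image: Image2D,
    result: DetectionResult,
    roi: RoiBox,
    beta: float = 0.6,
    max_bodies: int = 8,
    disc_height_frac: float = 0.5,
) -> DetectionResult:
    """Correct horizontal body positions using intervertebral-disc peaks.

    A disc template (width ``lx``, height ``disc_height_frac * ly``) is cut
    immediately above the user's vertebra ROI and matched through the image
    with the same peak-search procedure. A body whose column differs from
    the adjacent disc column estimate by more than 10% of ``ly`` has its
    column replaced; rows are never changed. The disc column estimate is the
    mean of the discs immediately above and below the body (their geometric
    offsets cancel on a straight, possibly tilted spine), or the single
    neighbour when only one exists.
    """
    if len(result.vb_centers) < 2:
        return result
    lx, ly = roi.lx, roi.ly
    dh = max(4, int(round(disc_height_frac * ly)))
    cr, cc = result.vb_centers[result.user_index]
    r1 = int(round(cr - ly / 2.0))
    r0 = r1 - dh
    c0 = int(round(cc - lx / 2.0))
    c1 = c0 + lx
    if r0 < 0 or c0 < 0 or c1 > image.shape[1] or r1 > image.shape[0]:
        logger.warning("disc template would exit the image; disc refinement skipped")
        return result
    template = image.pixels[r0:r1, c0:c1]
    if template.std() <= _VAR_EPS:
        logger.warning("disc template is constant; disc refinement skipped")
        return result

    try:
        dmap = compute_correlation_map(image, template)
        disc_centers, d_disc, _, _ = _search_centers(dmap, lx, dh, beta, max_bodies + 1)
    except DetectionError as exc:
        logger.warning("disc search failed (%s); disc refinement skipped", exc)
        return result
    # Discs interleave the bodies, so their spacing must match the body
    # reference distance; a mismatch means the disc template latched onto
    # something else and its columns cannot be trusted.
    if abs(d_disc - result.d) > 0.35 * result.d:
        logger.warning(
            "disc spacing %.1f inconsistent with body spacing %.1f; refinement skipped",
            d_disc,
            result.d,
        )
        return result

    # Positions are compared in the coordinate perpendicular to the spine
    # axis; for an upright spine (axis = vertical) this is exactly the
    # horizontal-location rule, and it stays valid when the image is tilted.
    axis = np.asarray(result.axis, dtype=float)
    normal = np.array([-axis[1], axis[0]])
    discs = np.asarray(disc_centers, dtype=float)
    disc_normal = discs @ normal
    vb = np.asarray(result.vb_centers, dtype=float)
    vb_normal = vb @ normal
    # Each body's nearest disc (within one reference distance).
    nearest = np.full(len(vb), -1)
    for i in range(len(vb)):
        sep = np.hypot(discs[:, 0] - vb[i, 0], discs[:, 1] - vb[i, 1])
        j = int(np.argmin(sep))
        if sep[j] <= result.d:
            nearest[i] = j
    matched = nearest >= 0
    if not matched.any():
        return result
    # The disc template is cut relative to the user ROI, so all disc peaks
    # share one systematic offset from the spine line (zero for an upright
    # spine); deviations are judged relative to its median.
    bias = float(np.median(disc_normal[nearest[matched]] - vb_normal[matched]))
    new_centers = []
    corrections = []
    for i, (vr, vc) in enumerate(result.vb_centers):
        if nearest[i] < 0:
            new_centers.append((vr, vc))
            continue
        shift = disc_normal[nearest[i]] - bias - vb_normal[i]
        if abs(shift) > 0.1 * ly:
            new_centers.append((vr + shift * normal[0], vc + shift * normal[1]))
            corrections.append(i)
        else:
            new_centers.append((vr, vc))
    return replace(
        result,
        vb_centers=new_centers,
        disc_centers=[(float(r), float(c)) for r, c in disc_centers],
        corrections=corrections,
    )


def detect(
    image: Image2D,
    roi: RoiBox,
    max_bodies: int = 8,
    beta: float = 0.6,
    disc_refine: bool = True,
) -> DetectionResult:
    """Full detection stage: correlation map, peak search, disc correction."""
    template = roi.extract(image)
    cmap = compute_correlation_map(image, template)
    result = find_vertebra_centers(cmap, roi, max_bodies=max_bodies, beta=beta)
    if disc_refine:
        result = refine_with_discs(image, result, roi, beta=beta, max_bodies=max_bodies)
    return result
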