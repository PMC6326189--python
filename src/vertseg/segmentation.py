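"""Hybrid graph-path / rule-based segmentation of one refined ROI.

Projection profiles of the ROI's edge map give four approximate boundary
coordinates (left/right columns, upper/lower rows) whose crossings are the
approximate vertices of the vertebral body. A band of half-width ``s``
around each side of that vertex rectangle, plus triangle pairs at the four
corners, partitions the boundary neighbourhood into the regions processed
below:

* superior / inferior bands (``U``, ``D``) — a minimum-cost monotone path
  across the band, where the step cost is the traversed pixel intensity, so
  the path settles into the dark cortical rim;
* lateral bands (``L``, ``R``) — the ROI intensities are k-means-clustered
  into 10 ordered levels and each horizontal line is classified into one of
  three cases by its valley/peak structure, yielding one boundary point per
  line;
* corner triangles — padded to parallelograms by replicating each line's
  terminal pixel, then handled with the band method (triangles adjoining
  U/D) or the line method (triangles adjoining L/R).

A cubic polynomial per side absorbs outlier points, and the four sides are
joined into a closed contour and rasterised into a mask.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from skimage import draw

from .core_io import BoundaryContour, Image2D, RoiBox, SegMask
from .roi_refinement import EdgeMap, ProjectionProfiles, detect_edges

__all__ = [
    "VertexEstimate",
    "AreaPartition",
    "ClusteredProfile",
    "BoundaryPath",
    "NoEdgeEvidenceError",
    "locate_vertices",
    "partition_areas",
    "segment_band_graph",
    "cluster_roi",
    "segment_line",
    "triangles_to_parallelograms",
    "smooth_contour",
    "segment_vertebra",
]

logger = logging.getLogger(__name__)


class NoEdgeEvidenceError(RuntimeError):
    """A projection half-profile carries no edge evidence for a side."""


@dataclass(frozen=True)
class VertexEstimate:
    """Approximate boundary coordinates: columns bL < bR, rows bU < bD."""

    bL: int
    bR: int
    bU: int
    bD: int


@dataclass
class AreaPartition:
    """Boolean membership rasters for the twelve boundary regions.

    ``bands`` holds U, D, L, R; ``triangles`` holds the corner halves
    (UL1/UR1/DL1/DR1 adjoin the U/D bands, UL2/UR2/DL2/DR2 adjoin L/R).
    """

    bands: dict
    triangles: dict
    spacing: int
    vertices: VertexEstimate

    def all_areas(self) -> dict:
        return {**self.bands, **self.triangles}


@dataclass
class ClusteredProfile:
    """Per-pixel intensity-cluster ranks in {1..k}, ascending with intensity."""

    ranks: np.ndarray
    k: int

    def line(self, index: int) -> np.ndarray:
        return self.ranks[index]


@dataclass
class BoundaryPath:
    """One boundary position per line of a band."""

    positions: np.ndarray  # row per column (U/D) or column per row (L/R)
    side: str
    cost: float = float("nan")


# ---------------------------------------------------------------------------
# Vertex location and area partition
# ---------------------------------------------------------------------------


def locate_vertices(profiles: ProjectionProfiles) -> VertexEstimate:
    """Approximate boundary lines from edge-projection argmaxima.

    Each coordinate is the argmax of its profile restricted to the matching
    half-interval (one border pixel excluded at each ROI edge); ties resolve
    toward the ROI border.
    """
    Px, Py = np.asarray(profiles.Px), np.asarray(profiles.Py)
    lx, ly = len(Px), len(Py)
    cx, cy = lx // 2, ly // 2

    def half_argmax(prof, lo, hi, prefer_high):
        seg = prof[lo:hi]
        if seg.size == 0 or seg.max() == 0:
            raise NoEdgeEvidenceError("no edge evidence for side")
        best = np.flatnonzero(seg == seg.max())
        return lo + int(best[-1] if prefer_high else best[0])

    return VertexEstimate(
        bL=half_argmax(Px, 1, cx, prefer_high=False),
        bR=half_argmax(Px, cx + 1, lx - 1, prefer_high=True),
        bU=half_argmax(Py, 1, cy, prefer_high=False),
        bD=half_argmax(Py, cy + 1, ly - 1, prefer_high=True),
    )


def partition_areas(
    vertices: VertexEstimate, spacing: int, shape: tuple[int, int]
) -> AreaPartition:
    """Partition the boundary neighbourhood into 4 bands + 8 corner triangles.

    Bands straddle the vertex rectangle's sides with half-width ``spacing``;
    each 2s x 2s corner square splits along its outer-to-inner diagonal into
    the triangle adjoining U/D (suffix 1) and the one adjoining L/R
    (suffix 2). All twelve regions are pairwise disjoint and cover an
    annular band around the vertex rectangle.
    """
    s = int(spacing)
    v = vertices
    if s < 2:
        raise ValueError("spacing must be >= 2 px")
    if (v.bR - v.bL) < 4 * s or (v.bD - v.bU) < 4 * s:
        raise ValueError(
            f"vertex rectangle ({v.bR - v.bL}x{v.bD - v.bU}) too small for spacing {s}"
        )
    ly, lx = shape
    if not (s <= v.bL and v.bR + s <= lx and s <= v.bU and v.bD + s <= ly):
        raise ValueError("bands would exit the ROI; vertices too close to the border")

    def rect(r0, r1, c0, c1):
        m = np.zeros(shape, dtype=bool)
        m[r0:r1, c0:c1] = True
        return m

    bands = {
        "U": rect(v.bU - s, v.bU + s, v.bL + s, v.bR - s),
        "D": rect(v.bD - s, v.bD + s, v.bL + s, v.bR - s),
        "L": rect(v.bU + s, v.bD - s, v.bL - s, v.bL + s),
        "R": rect(v.bU + s, v.bD - s, v.bR - s, v.bR + s),
    }
    rel = np.arange(2 * s)
    rr, cc = np.meshgrid(rel, rel, indexing="ij")
    main_upper = cc > rr  # above the outer->inner main diagonal
    anti_upper = (rr + cc) < (2 * s - 1)  # above the anti-diagonal

    def place(mask_2s, r0, c0):
        m = np.zeros(shape, dtype=bool)
        m[r0 : r0 + 2 * s, c0 : c0 + 2 * s] = mask_2s
        return m

    triangles = {
        "UL1": place(main_upper, v.bU - s, v.bL - s),
        "UL2": place(~main_upper, v.bU - s, v.bL - s),
        "UR1": place(anti_upper, v.bU - s, v.bR - s),
        "UR2": place(~anti_upper, v.bU - s, v.bR - s),
        "DL1": place(~anti_upper, v.bD - s, v.bL - s),
        "DL2": place(anti_upper, v.bD - s, v.bL - s),
        "DR1": place(~main_upper, v.bD - s, v.bR - s),
        "DR2": place(main_upper, v.bD - s, v.bR - s),
    }
    return AreaPartition(bands=bands, triangles=triangles, spacing=s, vertices=v)


# ---------------------------------------------------------------------------
# Band (graph) segmentation
# ---------------------------------------------------------------------------


def segment_band_graph(band_pixels: np.ndarray, orientation: str = "horizontal") -> BoundaryPath:
    """Minimum-cost monotone path across a band.

    The band is a chain graph: one node per column (for horizontal
    orientation), edges between vertically adjacent-or-equal rows of
    neighbouring columns, each step paying the intensity of the pixel it
    enters. The optimal path is found by dynamic programming — equivalent to
    the s/t minimum cut of the same chain graph — and splits the band into
    the regions above and below. Ties prefer staying level, then moving up.
    """
    band = np.asarray(band_pixels, dtype=float)
    if orientation == "vertical":
        return BoundaryPath(
            positions=segment_band_graph(band.T, "horizontal").positions,
            side="vertical",
        )
    n_rows, n_cols = band.shape
    if n_rows < 3 or n_cols < 5:
        raise ValueError(f"band too small for a boundary path: {band.shape}")

    cost = np.empty_like(band)
    step = np.zeros((n_rows, n_cols), dtype=np.int8)
    cost[:, 0] = band[:, 0]
    for j in range(1, n_cols):
        prev = cost[:, j - 1]
        # candidate predecessor rows in preference order: level, up, down
        stay = prev
        up = np.concatenate(([np.inf], prev[:-1]))
        down = np.concatenate((prev[1:], [np.inf]))
        stacked = np.stack([stay, up, down])
        best = np.argmin(stacked, axis=0)  # argmin returns first minimum
        cost[:, j] = band[:, j] + stacked[best, np.arange(n_rows)]
        step[:, j] = best
    r = int(np.argmin(cost[:, -1]))
    rows = np.empty(n_cols, dtype=int)
    rows[-1] = r
    for j in range(n_cols - 1, 0, -1):
        move = step[rows[j], j]
        rows[j - 1] = rows[j] - 1 if move == 1 else rows[j] + 1 if move == 2 else rows[j]
    return BoundaryPath(positions=rows, side="horizontal", cost=float(cost[rows[-1], -1]))


# ---------------------------------------------------------------------------
# Clustered line segmentation
# ---------------------------------------------------------------------------


def cluster_roi(roi_pixels: np.ndarray, k: int = 10, seed: int = 0) -> ClusteredProfile:
    """k-means-cluster ROI intensities into ``k`` ordered levels.

    Ranks 1..k follow ascending cluster-center intensity. If the patch has
    fewer distinct intensities than ``k``, k is reduced (logged). The
    clustering runs on the unique intensity values (weighted by count), so
    the result is deterministic under a fixed seed and independent of patch
    layout.
    """
    from sklearn.cluster import KMeans

    patch = np.asarray(roi_pixels, dtype=float)
    values, counts = np.unique(patch.ravel(), return_counts=True)
    k_eff = min(k, len(values))
    if k_eff < k:
        logger.info("reducing k from %d to %d distinct intensities", k, k_eff)
    if k_eff == 1:
        return ClusteredProfile(ranks=np.ones(patch.shape, dtype=int), k=1)
    km = KMeans(n_clusters=k_eff, n_init=10, random_state=seed)
    labels = km.fit_predict(values.reshape(-1, 1), sample_weight=counts)
    order = np.argsort(km.cluster_centers_.ravel(), kind="stable")
    rank_of = np.empty(k_eff, dtype=int)
    rank_of[order] = np.arange(1, k_eff + 1)
    value_rank = rank_of[labels]
    idx = np.searchsorted(values, patch.ravel())
    return ClusteredProfile(ranks=value_rank[idx].reshape(patch.shape), k=k_eff)


def _runs(y: np.ndarray):
    """Compress a 1-D integer profile into (value, start, end_inclusive) runs."""
    out = []
    start = 0
    for i in range(1, len(y) + 1):
        if i == len(y) or y[i] != y[start]:
            out.append((int(y[start]), start, i - 1))
            start = i
    return out


def classify_line(y: np.ndarray, side: str = "left") -> str:
    """Case label ('1', '2' or '3') for one clustered line profile.

    The cases are mutually exclusive and exhaustive: Case 3 has no interior
    valley; Case 1 has a valley below the reference value R with a farther
    peak at least 2 cluster stages above it and itself reaching R; every
    remaining valley profile is Case 2.
    """
    return _segment_line_canonical(_canonical(y, side))[1]


def _canonical(y: np.ndarray, side: str) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    if y.ndim != 1 or y.size < 2:
        raise ValueError("line profile must be 1-D with at least 2 samples")
    return y[::-1] if side == "right" else y


def _segment_line_canonical(y: np.ndarray) -> tuple[int, str]:
    """Boundary index and case for a profile with its base at the last index."""
    n = len(y)
    runs = _runs(y)
    peaks = []  # run indices that are local maxima
    valleys = []  # interior runs that are local minima
    for ri, (val, a, b) in enumerate(runs):
        left = runs[ri - 1][0] if ri > 0 else None
        right = runs[ri + 1][0] if ri < len(runs) - 1 else None
        higher = (left is None or val > left) and (right is None or val > right)
        lower = left is not None and right is not None and val < left and val < right
        if higher:
            peaks.append(ri)
        if lower:
            valleys.append(ri)

    # Base: the profile end if it lies on a peak run, else the peak nearest it.
    last_peak = peaks[-1]
    B = n - 1 if runs[last_peak][2] == n - 1 else runs[last_peak][2]
    yB = int(y[B])
    R = math.ceil(yB / 2)

    def point_M() -> int:
        target = math.ceil(yB / 3)
        hits = np.flatnonzero(y == target)
        if hits.size == 0:
            logger.info("no point attains ceil(Y(B)/3)=%d; using band end", target)
            return 0
        return int(hits[np.argmin(np.abs(hits - B))])

    if not valleys:
        return point_M(), "3"

    # Qualifying peak: nearest to B with a valley < R toward B that it
    # exceeds by >= 2 cluster stages.
    base_run = next(ri for ri, (_, a, b) in enumerate(runs) if a <= B <= b)
    qualifying = []
    for ri in peaks:
        if ri >= base_run:
            continue
        between = [vi for vi in valleys if ri < vi < base_run]
        good = [vi for vi in between if runs[vi][0] < R and runs[ri][0] - runs[vi][0] >= 2]
        if good:
            qualifying.append(ri)
    strong = [ri for ri in qualifying if runs[ri][0] >= R]
    if strong:
        P = runs[max(strong)][2]  # peak point closest to B
        lo, hi = P + 1, B  # strictly between P and the base
        if lo < hi:
            seg = y[lo:hi]
            best = np.flatnonzero(seg == seg.min())
            return lo + int(best[-1]), "1"  # tie -> closest to B
        return point_M(), "1"
    return point_M(), "2"


def segment_line(profile: np.ndarray, side: str) -> int:
    """Boundary point index for one clustered line.

    ``side`` fixes the scan geometry: for the left band the base lies at the
    interior (last) index and the scan runs toward index 0; the right band
    is the mirror image. Case 1 returns the minimum between the qualifying
    peak and the base; Cases 2 and 3 return the point nearest the base at
    one third of the base level (band end as fallback).
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    y = _canonical(profile, side)
    e, _ = _segment_line_canonical(y)
    return int(len(y) - 1 - e) if side == "right" else int(e)


# ---------------------------------------------------------------------------
# Corner triangles
# ---------------------------------------------------------------------------


def triangles_to_parallelograms(
    patch: np.ndarray, tri_mask: np.ndarray, axis: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pad a triangular region to a full rectangle by replicating endpoints.

    Along ``axis`` (0 = pad along rows so each *column* becomes full length,
    1 = pad along columns per *row*), invalid cells take the value of the
    nearest valid cell of their line; fully empty lines copy their nearest
    non-empty neighbour. Returns the padded array plus per-line first/last
    valid indices for projecting boundary points back onto the hypotenuse.
    """
    patch = np.asarray(patch, dtype=float)
    mask = np.asarray(tri_mask, dtype=bool)
    if not mask.any():
        raise ValueError("triangular area is empty")
    if axis == 0:
        padded, lo, hi = triangles_to_parallelograms(patch.T, mask.T, axis=1)
        return padded.T, lo, hi
    n_rows, n_cols = patch.shape
    padded = np.array(patch)
    lo = np.full(n_rows, -1)
    hi = np.full(n_rows, -1)
    for i in range(n_rows):
        valid = np.flatnonzero(mask[i])
        if valid.size == 0:
            continue
        lo[i], hi[i] = valid[0], valid[-1]
        padded[i, : lo[i]] = patch[i, lo[i]]
        padded[i, hi[i] + 1 :] = patch[i, hi[i]]
    empty = np.flatnonzero(lo < 0)
    filled = np.flatnonzero(lo >= 0)
    for i in empty:
        j = filled[np.argmin(np.abs(filled - i))]
        padded[i] = padded[j]
        lo[i], hi[i] = lo[j], hi[j]
    return padded, lo, hi


# ---------------------------------------------------------------------------
# Contour smoothing and orchestration
# ---------------------------------------------------------------------------


def _smooth_side(coords: np.ndarray, positions: np.ndarray, delta: float) -> np.ndarray:
    """Cubic-fit outlier replacement for one side's boundary positions."""
    if len(positions) < 4:
        logger.info("side with %d points kept raw", len(positions))
        return positions.astype(float)
    coef = np.polyfit(coords, positions, 3)
    fitted = np.polyval(coef, coords)
    out = positions.astype(float)
    bad = np.abs(out - fitted) > delta
    out[bad] = fitted[bad]
    return out


def smooth_contour(
    sides: dict,
    delta: float = 3.0,
) -> BoundaryContour:
    """Fit a cubic per side, replace outliers beyond ``delta`` px, close the ring.

    ``sides`` maps 'upper'/'lower' to (cols, rows) and 'left'/'right' to
    (rows, cols) coordinate pairs, each ordered by its running coordinate.
    """
    u_cols, u_rows = sides["upper"]
    d_cols, d_rows = sides["lower"]
    l_rows, l_cols = sides["left"]
    r_rows, r_cols = sides["right"]
    u_rows = _smooth_side(np.asarray(u_cols, float), np.asarray(u_rows, float), delta)
    d_rows = _smooth_side(np.asarray(d_cols, float), np.asarray(d_rows, float), delta)
    l_cols = _smooth_side(np.asarray(l_rows, float), np.asarray(l_cols, float), delta)
    r_cols = _smooth_side(np.asarray(r_rows, float), np.asarray(r_cols, float), delta)
    return BoundaryContour(
        upper=np.column_stack([u_rows, u_cols]),
        right=np.column_stack([r_rows, r_cols]),
        lower=np.column_stack([d_rows, d_cols])[::-1],
        left=np.column_stack([l_rows, l_cols])[::-1],
        closed=True,
    )


def segment_vertebra(
    image: Image2D,
    refined_roi: RoiBox,
    *,
    spacing_frac: float = 0.08,
    k_clusters: int = 10,
    delta: float = 3.0,
    canny_sigma: float = 1.4,
    seed: int = 0,
) -> tuple[SegMask, BoundaryContour]:
    """Segment one vertebral body inside a refined ROI.

    Runs vertex location, area partition, band/line/corner segmentation and
    cubic smoothing, then rasterises the closed contour into a full-image
    mask. The returned contour is in image coordinates.
    """
    s_target = max(3, math.ceil(spacing_frac * min(refined_roi.lx, refined_roi.ly)))
    # pad the working crop so boundary bands can straddle a body that touches
    # the refined ROI edge (the contour may lie in this extension)
    pad = s_target + 2
    work_roi = RoiBox(
        center=refined_roi.center,
        lx=refined_roi.lx + 2 * pad,
        ly=refined_roi.ly + 2 * pad,
        angle=refined_roi.angle,
    )
    crop = work_roi.extract(image, mode="nearest")
    ly, lx = crop.shape
    # vertices come from the unpadded ROI (refined to contain the body and
    # little else — the padding would pull disc edges into the projections)
    inner = refined_roi.extract(image, mode="nearest")
    edges = detect_edges(inner, sigma=canny_sigma)
    profiles = ProjectionProfiles.from_edges(edges)
    v_in = locate_vertices(profiles)
    v = VertexEstimate(
        bL=v_in.bL + pad, bR=v_in.bR + pad, bU=v_in.bU + pad, bD=v_in.bD + pad
    )

    s = min(s_target, (v.bR - v.bL) // 4, (v.bD - v.bU) // 4, v.bL, v.bU, lx - v.bR, ly - v.bD)
    if s < 2:
        raise ValueError(f"vertex rectangle too tight for any band spacing (s={s})")
    refined_roi = work_roi
    part = partition_areas(v, s, crop.shape)
    clustered = cluster_roi(crop, k=k_clusters, seed=seed)

    def band_box(mask):
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        return rows[0], rows[-1] + 1, cols[0], cols[-1] + 1

    # --- superior / inferior: corner-triangle paths + band path, per column
    def horizontal_side(name, tri_l, tri_r):
        r0, r1, c0, c1 = band_box(part.bands[name])
        path = segment_band_graph(crop[r0:r1, c0:c1]).positions + r0
        cols = np.arange(c0, c1)
        seg_cols, seg_rows = [cols], [path]
        for tri_name in (tri_l, tri_r):
            tmask = part.triangles[tri_name]
            tr0, tr1, tc0, tc1 = band_box(tmask)
            padded, lo, hi = triangles_to_parallelograms(
                crop[tr0:tr1, tc0:tc1], tmask[tr0:tr1, tc0:tc1], axis=0
            )
            tpath = segment_band_graph(padded).positions
            tpath = np.clip(tpath, lo, hi) + tr0  # back onto the hypotenuse
            seg_cols.append(np.arange(tc0, tc1))
            seg_rows.append(tpath)
        cols = np.concatenate(seg_cols)
        rows = np.concatenate(seg_rows)
        order = np.argsort(cols, kind="stable")
        return cols[order], rows[order]

    u_cols, u_rows = horizontal_side("U", "UL1", "UR1")
    d_cols, d_rows = horizontal_side("D", "DL1", "DR1")

    # --- lateral: per-line rule on clustered ranks + corner-triangle lines
    def lateral_side(name, tri_u, tri_d, side):
        r0, r1, c0, c1 = band_box(part.bands[name])
        rows = np.arange(r0, r1)
        cols = np.array(
            [c0 + segment_line(clustered.ranks[i, c0:c1], side) for i in rows]
        )
        seg_rows, seg_cols = [rows], [cols]
        for tri_name in (tri_u, tri_d):
            tmask = part.triangles[tri_name]
            tr0, tr1, tc0, tc1 = band_box(tmask)
            padded, lo, hi = triangles_to_parallelograms(
                clustered.ranks[tr0:tr1, tc0:tc1].astype(float),
                tmask[tr0:tr1, tc0:tc1],
                axis=1,
            )
            trows = np.arange(tr0, tr1)
            tcols = np.array(
                [
                    np.clip(segment_line(padded[i], side), lo[i], hi[i]) + tc0
                    for i in range(padded.shape[0])
                ]
            )
            seg_rows.append(trows)
            seg_cols.append(tcols)
        rows = np.concatenate(seg_rows)
        cols = np.concatenate(seg_cols)
        order = np.argsort(rows, kind="stable")
        return rows[order], cols[order]

    l_rows, l_cols = lateral_side("L", "UL2", "DL2", "left")
    r_rows, r_cols = lateral_side("R", "UR2", "DR2", "right")

    contour_local = smooth_contour(
        {
            "upper": (u_cols, u_rows),
            "lower": (d_cols, d_rows),
            "left": (l_rows, l_cols),
            "right": (r_rows, r_cols),
        },
        delta=delta,
    )

    # map to image coordinates and rasterise
    contour = BoundaryContour(
        upper=refined_roi.to_image_coords(contour_local.upper),
        right=refined_roi.to_image_coords(contour_local.right),
        lower=refined_roi.to_image_coords(contour_local.lower),
        left=refined_roi.to_image_coords(contour_local.left),
        closed=True,
    )
    ring = contour.polygon()
    rr, cc = draw.polygon(ring[:, 0], ring[:, 1], shape=image.shape)
    mask = np.zeros(image.shape, dtype=np.uint8)
    mask[rr, cc] = 1
    # the contour itself runs through body tissue (mid-rim), so it belongs
    # to the mask
    pr, pc = draw.polygon_perimeter(ring[:, 0], ring[:, 1], shape=image.shape)
    mask[pr, pc] = 1
    mask = _largest_component(mask)
    return SegMask(mask), contour


def _largest_component(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage as ndi

    lab, n = ndi.label(mask)  # 4-connectivity
    if n <= 1:
        return mask
    sizes = ndi.sum(mask, lab, index=range(1, n + 1))
    return (lab == (1 + int(np.argmax(sizes)))).astype(np.uint8)
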