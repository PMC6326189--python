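"""Synthetic sagittal lumbar-spine phantom with exact ground truth.

The phantom emulates the geometry the segmentation pipeline assumes: a
vertical stack of bright, rounded-rectangular vertebral bodies bounded by a
dark cortical rim, separated by thinner, brighter intervertebral discs, on a
mid-gray background (T2-like contrast ordering disc > body > background >
rim). Every geometric fact — per-body masks, centers, disc centers, rim
outlines — is available exactly, which makes each pipeline stage testable
without MR data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core_io import Image2D, SegMask, _rotation_matrix

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom", "rotate_dataset"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic spine image.

    Defaults describe a mid-sagittal lumbar acquisition at 0.39 mm/px:
    bodies ~25 x 17 mm (64 x 44 px), center-to-center pitch 25 mm (64 px),
    and a 2 px cortical rim. ``rotations`` holds one angle per body
    (degrees CCW); ``jitter_frac`` perturbs each body's size by up to that
    fraction. ``noise_sigma`` is additive Gaussian noise as a fraction of
    the dynamic range; ``bias_field`` is the amplitude of a smooth
    multiplicative quadratic inhomogeneity.
    """

    n_bodies: int = 5
    body_size: tuple[int, int] = (64, 44)  # (lx, ly) px
    jitter_frac: float = 0.03
    pitch: int = 64
    rotations: tuple[float, ...] | float = 0.0
    intensities: dict = field(
        default_factory=lambda: {
            "body": 0.55,
            "rim": 0.05,
            "disc": 0.85,
            "background": 0.20,
        }
    )
    noise_sigma: float = 0.0
    bias_field: float = 0.0
    rim_thickness: int = 2
    col_offsets: tuple[float, ...] | float = 0.0
    seed: int = 0

    def rotations_list(self) -> list[float]:
        r = self.rotations
        return [float(r)] * self.n_bodies if np.isscalar(r) else [float(a) for a in r]

    def col_offsets_list(self) -> list[float]:
        c = self.col_offsets
        return [float(c)] * self.n_bodies if np.isscalar(c) else [float(v) for v in c]

    def validate(self) -> None:
        problems = []
        if not (2 <= self.n_bodies <= 10):
            problems.append(f"n_bodies={self.n_bodies} outside [2, 10]")
        lx, ly = self.body_size
        if lx < 16 or ly < 16:
            problems.append(f"body_size={self.body_size} too small (min 16 px)")
        if self.pitch <= ly:
            problems.append(f"pitch={self.pitch} must exceed body height ly={ly}")
        vals = sorted(self.intensities[k] for k in ("body", "rim", "disc", "background"))
        if min(b - a for a, b in zip(vals, vals[1:])) < 0.1:
            problems.append("intensities must be pairwise distinct by >= 0.1")
        if not all(0.0 <= v <= 1.0 for v in vals):
            problems.append("intensities must lie in [0, 1]")
        if len(self.rotations_list()) != self.n_bodies:
            problems.append("rotations length must equal n_bodies")
        if any(abs(a) > 45 for a in self.rotations_list()):
            problems.append("per-body rotations must be within +-45 degrees")
        if self.noise_sigma < 0 or self.bias_field < 0 or self.jitter_frac < 0:
            problems.append("noise_sigma, bias_field, jitter_frac must be >= 0")
        if problems:
            raise ValueError("invalid PhantomSpec: " + "; ".join(problems))


@dataclass
class PhantomTruth:
    """Exact pre-noise geometry of a generated phantom."""

    masks: list[SegMask]
    centers: list[tuple[float, float]]  # (row, col), superior -> inferior
    disc_centers: list[tuple[float, float]]
    rim_polygons: list[np.ndarray]  # (N, 2) outer-outline points per body
    body_sizes: list[tuple[float, float]]  # per-body (lx, ly) after jitter
    rotations: list[float]


_SUPERELLIPSE_P = 4.0  # rounded-rectangle exponent


def _superellipse_inside(
    dr: np.ndarray, dc: np.ndarray, half_w: float, half_h: float, angle: float
) -> np.ndarray:
    """Membership test for a rotated rounded rectangle centered at the origin."""
    rot = _rotation_matrix(-angle)  # image offsets -> body-local offsets
    lr = rot[0, 0] * dr + rot[0, 1] * dc
    lc = rot[1, 0] * dr + rot[1, 1] * dc
    p = _SUPERELLIPSE_P
    return (np.abs(lc / half_w) ** p + np.abs(lr / half_h) ** p) <= 1.0


def _superellipse_outline(
    center: tuple[float, float], half_w: float, half_h: float, angle: float, n: int = 256
) -> np.ndarray:
    t = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
    p = _SUPERELLIPSE_P
    lc = np.sign(np.cos(t)) * np.abs(np.cos(t)) ** (2.0 / p) * half_w
    lr = np.sign(np.sin(t)) * np.abs(np.sin(t)) ** (2.0 / p) * half_h
    pts = np.stack([lr, lc], axis=1) @ _rotation_matrix(angle).T
    return pts + np.asarray(center)


def generate_phantom(spec: PhantomSpec) -> tuple[Image2D, PhantomTruth]:
    """Render a phantom image and its exact ground truth.

    Deterministic under a fixed ``spec.seed``. Truth masks record the
    pre-noise geometry (body interior plus cortical rim).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lx, ly = spec.body_size
    rotations = spec.rotations_list()
    col_offsets = spec.col_offsets_list()

    margin_r = max(int(0.75 * spec.pitch), ly)
    margin_c = max(48, int(0.75 * lx))
    n_rows = 2 * margin_r + (spec.n_bodies - 1) * spec.pitch
    n_cols = 2 * margin_c + lx
    if n_cols % 2 == 0:
        n_cols += 1  # odd width puts body centers on integer columns
    mid_col = (n_cols - 1) / 2.0

    img = np.full((n_rows, n_cols), spec.intensities["background"], dtype=float)
    rows_g, cols_g = np.mgrid[0:n_rows, 0:n_cols].astype(float)

    centers: list[tuple[float, float]] = []
    sizes: list[tuple[float, float]] = []
    masks: list[SegMask] = []
    outlines: list[np.ndarray] = []
    for i in range(spec.n_bodies):
        jw = 1.0 + rng.uniform(-spec.jitter_frac, spec.jitter_frac)
        jh = 1.0 + rng.uniform(-spec.jitter_frac, spec.jitter_frac)
        w, h = lx * jw, ly * jh
        cr = margin_r + i * spec.pitch
        cc = mid_col + col_offsets[i]
        dr, dc = rows_g - cr, cols_g - cc
        outer = _superellipse_inside(dr, dc, w / 2.0, h / 2.0, rotations[i])
        inner = _superellipse_inside(
            dr, dc, w / 2.0 - spec.rim_thickness, h / 2.0 - spec.rim_thickness, rotations[i]
        )
        img[outer] = spec.intensities["rim"]
        img[inner] = spec.intensities["body"]
        centers.append((float(cr), float(cc)))
        sizes.append((w, h))
        masks.append(SegMask(outer.astype(np.uint8), label=i + 1))
        outlines.append(_superellipse_outline((cr, cc), w / 2.0, h / 2.0, rotations[i]))

    # Discs: between consecutive bodies plus one above / below the stack.
    disc_centers: list[tuple[float, float]] = []
    gap = spec.pitch - ly
    disc_h = max(4.0, min(0.6 * gap, 12.0))
    disc_w = 0.85 * lx
    disc_rows = (
        [margin_r - spec.pitch / 2.0]
        + [margin_r + (i + 0.5) * spec.pitch for i in range(spec.n_bodies - 1)]
        + [margin_r + (spec.n_bodies - 0.5) * spec.pitch]
    )
    body_any = np.zeros((n_rows, n_cols), dtype=bool)
    for m in masks:
        body_any |= m.pixels.astype(bool)
    for k, dr_row in enumerate(disc_rows):
        if k == 0:
            dcc = mid_col + col_offsets[0]
            tilt = rotations[0]
        elif k == len(disc_rows) - 1:
            dcc = mid_col + col_offsets[-1]
            tilt = rotations[-1]
        else:
            dcc = mid_col + (col_offsets[k - 1] + col_offsets[k]) / 2.0
            tilt = (rotations[k - 1] + rotations[k]) / 2.0
        dr, dc = rows_g - dr_row, cols_g - dcc
        rot = _rotation_matrix(-tilt)  # discs follow the adjacent endplates
        lr = rot[0, 0] * dr + rot[0, 1] * dc
        lc = rot[1, 0] * dr + rot[1, 1] * dc
        disc = ((lc / (disc_w / 2.0)) ** 2 + (lr / (disc_h / 2.0)) ** 2) <= 1.0
        img[disc & ~body_any] = spec.intensities["disc"]
        disc_centers.append((float(dr_row), float(dcc)))

    if spec.bias_field > 0:
        u = (rows_g / (n_rows - 1)) * 2 - 1
        v = (cols_g / (n_cols - 1)) * 2 - 1
        coef = rng.uniform(-1.0, 1.0, size=5)
        poly = coef[0] * u + coef[1] * v + coef[2] * u * v + coef[3] * u * u + coef[4] * v * v
        img = img * (1.0 + spec.bias_field * poly / max(1e-9, np.abs(poly).max()))
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    image = Image2D(img)
    truth = PhantomTruth(
        masks=masks,
        centers=centers,
        disc_centers=disc_centers,
        rim_polygons=outlines,
        body_sizes=sizes,
        rotations=rotations,
    )
    return image, truth


def _rotated_canvas(shape: tuple[int, int], angle: float):
    """Output shape, centers and forward map for a bounds-preserving rotation."""
    rot = _rotation_matrix(angle)
    h, w = shape
    cin = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    corners = np.array([[0, 0], [0, w - 1], [h - 1, 0], [h - 1, w - 1]], dtype=float)
    rc = (corners - cin) @ rot.T
    out_h = int(math.ceil(rc[:, 0].max() - rc[:, 0].min())) + 1
    out_w = int(math.ceil(rc[:, 1].max() - rc[:, 1].min())) + 1
    cout = np.array([(out_h - 1) / 2.0, (out_w - 1) / 2.0])
    return (out_h, out_w), cin, cout, rot


def _warp(arr: np.ndarray, angle: float, order: int, cval: float) -> np.ndarray:
    out_shape, cin, cout, rot = _rotated_canvas(arr.shape, angle)
    rows, cols = np.mgrid[0 : out_shape[0], 0 : out_shape[1]].astype(float)
    inv = _rotation_matrix(-angle)
    dr, dc = rows - cout[0], cols - cout[1]
    src_r = cin[0] + inv[0, 0] * dr + inv[0, 1] * dc
    src_c = cin[1] + inv[1, 0] * dr + inv[1, 1] * dc
    return ndimage.map_coordinates(arr, [src_r, src_c], order=order, mode="constant", cval=cval)


def rotate_dataset(
    image: Image2D, truth: PhantomTruth, angle: float
) -> tuple[Image2D, PhantomTruth]:
    """Rotate an image and all its ground truth together by ``angle`` degrees CCW.

    The canvas expands so nothing is clipped; the image is resampled with
    bilinear interpolation, masks with nearest-neighbour, and centers and
    outlines are transformed analytically.
    """
    if abs(angle) > 45:
        raise ValueError("rotate_dataset supports |angle| <= 45 degrees")
    if angle == 0:
        return image, truth
    bg = float(np.median(image.pixels))
    new_px = _warp(image.pixels, angle, order=1, cval=bg)
    out_shape, cin, cout, rot = _rotated_canvas(image.pixels.shape, angle)

    def fwd(points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return (pts - cin) @ rot.T + cout

    new_masks = [
        SegMask(_warp(m.pixels.astype(float), angle, order=0, cval=0.0).astype(np.uint8) > 0,
                label=m.label)
        for m in truth.masks
    ]
    new_truth = PhantomTruth(
        masks=[SegMask(m.pixels, label=m.label) for m in new_masks],
        centers=[tuple(p) for p in fwd(truth.centers)],
        disc_centers=[tuple(p) for p in fwd(truth.disc_centers)],
        rim_polygons=[fwd(poly) for poly in truth.rim_polygons],
        body_sizes=list(truth.body_sizes),
        rotations=[r + angle for r in truth.rotations],
    )
    return (
        Image2D(np.clip(new_px, 0.0, 1.0), image.pixel_spacing, image.slice_thickness),
        new_truth,
    )
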