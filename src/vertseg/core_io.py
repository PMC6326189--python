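"""Domain types and image/mask I/O shared by every pipeline stage.

Conventions used throughout the package
---------------------------------------
* Pixel coordinates are ``(row, col)``, 0-based, row increasing downward
  (superior to inferior in a sagittal spine image).
* Angles are degrees, positive counter-clockwise in the displayed image,
  and restricted to ``(-90, 90]``.
* Intensities are normalised to ``[0, 1]`` on load; every decision rule in
  the pipeline is contrast-relative, so absolute scale never matters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "Image2D",
    "RoiBox",
    "SegMask",
    "BoundaryContour",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "round_half_away",
]

#: Default in-plane resolution (mm/pixel) of a typical sagittal T2 spine protocol.
DEFAULT_PIXEL_SPACING = 0.39
#: Default slice thickness (mm).
DEFAULT_SLICE_THICKNESS = 3.0

_MIN_IMAGE_SIDE = 32


def round_half_away(x: float | np.ndarray) -> np.ndarray:
    """Round half away from zero (unlike numpy's banker's rounding)."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)


def _rotation_matrix(angle_deg: float) -> np.ndarray:
    """Rotation of (row, col) offset vectors by ``angle_deg`` CCW in display space."""
    t = math.radians(angle_deg)
    return np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])


@dataclass(frozen=True)
class Image2D:
    """A 2-D grayscale raster with optional physical spacing.

    Parameters
    ----------
    pixels : ndarray
        2-D float array, intensities in ``[0, 1]`` after normalisation.
    pixel_spacing : float
        In-plane resolution in mm/pixel.
    slice_thickness : float
        Through-plane thickness in mm (used only for volume reports).
    """

    pixels: np.ndarray
    pixel_spacing: float = DEFAULT_PIXEL_SPACING
    slice_thickness: float = DEFAULT_SLICE_THICKNESS

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"Image2D requires a 2-D raster, got shape {px.shape}")
        if min(px.shape) < _MIN_IMAGE_SIDE:
            raise ValueError(
                f"Image2D must be at least {_MIN_IMAGE_SIDE}x{_MIN_IMAGE_SIDE}, got {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise ValueError("Image2D pixels must be finite")
        if px.min() < 0:
            raise ValueError("Image2D pixels must be non-negative")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @classmethod
    def from_array(
        cls,
        arr: np.ndarray,
        pixel_spacing: float = DEFAULT_PIXEL_SPACING,
        slice_thickness: float = DEFAULT_SLICE_THICKNESS,
        normalize: bool = True,
    ) -> "Image2D":
        """Build an image from a raw array, rescaling intensities to [0, 1]."""
        arr = np.asarray(arr, dtype=float)
        if normalize:
            lo, hi = float(arr.min()), float(arr.max())
            arr = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
        return cls(arr, pixel_spacing=pixel_spacing, slice_thickness=slice_thickness)


@dataclass(frozen=True)
class RoiBox:
    """A rectangular region of interest locating one vertebral body.

    The box is stored unrotated (``lx`` wide, ``ly`` tall) plus a rotation
    ``angle``; pixel extraction resamples the image so the box content
    appears axis-aligned in the returned crop.
    """

    center: tuple[float, float]  # (row, col)
    lx: int
    ly: int
    angle: float = 0.0

    def __post_init__(self) -> None:
        if self.lx < 8 or self.ly < 8:
            raise ValueError(f"RoiBox sides must be >= 8 px, got lx={self.lx}, ly={self.ly}")
        if not (-90.0 < self.angle <= 90.0):
            raise ValueError(f"RoiBox angle must lie in (-90, 90], got {self.angle}")
        object.__setattr__(self, "center", (float(self.center[0]), float(self.center[1])))
        object.__setattr__(self, "lx", int(self.lx))
        object.__setattr__(self, "ly", int(self.ly))

    def local_offsets(self) -> tuple[np.ndarray, np.ndarray]:
        """Centered (d_row, d_col) offset grids of shape (ly, lx)."""
        dr = np.arange(self.ly, dtype=float) - (self.ly - 1) / 2.0
        dc = np.arange(self.lx, dtype=float) - (self.lx - 1) / 2.0
        return np.meshgrid(dr, dc, indexing="ij")

    def extract(self, image: Image2D, mode: str = "constant") -> np.ndarray:
        """Resample the box content as an axis-aligned (ly, lx) crop.

        A box with angle ``a`` over a vertebra rotated by ``a`` yields a crop
        in which the vertebra is upright; bilinear interpolation is used and
        out-of-image samples are zero-padded (``mode="nearest"`` replicates
        the border instead, useful when spurious step edges must be avoided).
        """
        drg, dcg = self.local_offsets()
        rot = _rotation_matrix(self.angle)
        rows = self.center[0] + rot[0, 0] * drg + rot[0, 1] * dcg
        cols = self.center[1] + rot[1, 0] * drg + rot[1, 1] * dcg
        return ndimage.map_coordinates(
            image.pixels, [rows, cols], order=1, mode=mode, cval=0.0
        )

    def to_image_coords(self, points: np.ndarray) -> np.ndarray:
        """Map (row, col) points from crop coordinates back into the image frame."""
        pts = np.asarray(points, dtype=float)
        local = pts - np.array([(self.ly - 1) / 2.0, (self.lx - 1) / 2.0])
        return local @ _rotation_matrix(self.angle).T + np.asarray(self.center)

    def corners(self) -> np.ndarray:
        """The four box corners in image coordinates, in drawing order."""
        h, w = (self.ly - 1) / 2.0, (self.lx - 1) / 2.0
        local = np.array([[-h, -w], [-h, w], [h, w], [h, -w]])
        return local @ _rotation_matrix(self.angle).T + np.asarray(self.center)

    def intersects(self, shape: tuple[int, int]) -> bool:
        c = self.corners()
        return bool(
            (c[:, 0].max() >= 0)
            and (c[:, 0].min() <= shape[0] - 1)
            and (c[:, 1].max() >= 0)
            and (c[:, 1].min() <= shape[1] - 1)
        )

    def with_angle(self, angle: float) -> "RoiBox":
        return replace(self, angle=float(angle))

    def to_json(self) -> dict:
        return {
            "center": [self.center[0], self.center[1]],
            "lx": self.lx,
            "ly": self.ly,
            "angle": self.angle,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "RoiBox":
        return cls(
            center=tuple(obj["center"]),
            lx=int(obj["lx"]),
            ly=int(obj["ly"]),
            angle=float(obj.get("angle", 0.0)),
        )


@dataclass(frozen=True)
class SegMask:
    """Binary raster labelling one vertebral body's pixels.

    ``label`` is the vertebra index, 1 being the most superior detected body.
    """

    pixels: np.ndarray
    label: int = 1

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("SegMask requires a 2-D raster")
        uniq = np.unique(px)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("SegMask values must be 0/1")
        object.__setattr__(self, "pixels", px.astype(np.uint8))
        object.__setattr__(self, "label", int(self.label))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.pixels.sum())


@dataclass
class BoundaryContour:
    """One vertebra outline as four ordered per-side point lists.

    Sides are stored as (row, col) float arrays: ``upper`` left-to-right,
    ``right`` top-to-bottom, ``lower`` right-to-left, ``left`` bottom-to-top,
    so that concatenation walks the outline clockwise in display space.
    """

    upper: np.ndarray
    right: np.ndarray
    lower: np.ndarray
    left: np.ndarray
    closed: bool = True

    def polygon(self) -> np.ndarray:
        """All outline points concatenated into one (N, 2) closed ring."""
        return np.vstack([self.upper, self.right, self.lower, self.left])

    def to_json(self) -> dict:
        return {
            "upper": np.asarray(self.upper).tolist(),
            "right": np.asarray(self.right).tolist(),
            "lower": np.asarray(self.lower).tolist(),
            "left": np.asarray(self.left).tolist(),
            "closed": self.closed,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "BoundaryContour":
        return cls(
            upper=np.asarray(obj["upper"], dtype=float),
            right=np.asarray(obj["right"], dtype=float),
            lower=np.asarray(obj["lower"], dtype=float),
            left=np.asarray(obj["left"], dtype=float),
            closed=bool(obj.get("closed", True)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json()))

    @classmethod
    def load(cls, path: str | Path) -> "BoundaryContour":
        return cls.from_json(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_FORMATS = ("png", "tiff", "dicom", "nifti")


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    suffix = path.suffix.lower()
    return {
        ".png": "png",
        ".tif": "tiff",
        ".tiff": "tiff",
        ".dcm": "dicom",
        ".dicom": "dicom",
    }.get(suffix, "")


def read_image(
    path: str | Path,
    format: str | None = None,
    slice_index: int | str | None = "mid",
) -> Image2D:
    """Read a 2-D grayscale image (PNG, TIFF, DICOM or NIfTI).

    Multi-slice NIfTI volumes yield one sagittal slice: the requested
    ``slice_index`` along the last axis, ``"mid"`` (default) for the
    mid-sagittal slice, or an error if ``slice_index`` is ``None``.
    Physical spacing is read from DICOM/NIfTI headers when present.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise IOError(f"cannot determine image format of {path}; pass format=")

    spacing, thickness = DEFAULT_PIXEL_SPACING, DEFAULT_SLICE_THICKNESS
    if fmt in ("png", "tiff"):
        import imageio.v3 as iio

        try:
            arr = np.asarray(iio.imread(path))
        except Exception as exc:  # pragma: no cover - backend specific
            raise IOError(f"unreadable {fmt} file: {path}") from exc
        if arr.ndim == 3:  # RGB(A) -> luminance
            arr = arr[..., :3].astype(float) @ np.array([0.2126, 0.7152, 0.0722])
    elif fmt == "dicom":
        import pydicom

        try:
            ds = pydicom.dcmread(str(path))
            arr = ds.pixel_array.astype(float)
        except Exception as exc:
            raise IOError(f"unreadable DICOM file: {path}") from exc
        if getattr(ds, "PixelSpacing", None):
            spacing = float(ds.PixelSpacing[0])
        if getattr(ds, "SliceThickness", None):
            thickness = float(ds.SliceThickness)
    else:  # nifti
        import nibabel as nib

        try:
            img = nib.load(str(path))
            arr = np.asarray(img.get_fdata(), dtype=float)
        except Exception as exc:
            raise IOError(f"unreadable NIfTI file: {path}") from exc
        zooms = img.header.get_zooms()
        if len(zooms) >= 2:
            spacing = float(zooms[0])
        if len(zooms) >= 3:
            thickness = float(zooms[2])
        if arr.ndim == 3:
            n_slices = arr.shape[-1]
            if n_slices == 1:
                arr = arr[..., 0]
            elif slice_index is None:
                raise IOError(
                    f"{path} has {n_slices} slices; pass slice_index (or 'mid')"
                )
            else:
                idx = n_slices // 2 if slice_index == "mid" else int(slice_index)
                arr = arr[..., idx]
    if arr.ndim != 2:
        raise IOError(f"{path} did not yield a 2-D raster (shape {arr.shape})")
    return Image2D.from_array(arr, pixel_spacing=spacing, slice_thickness=thickness)


def write_image(image: Image2D, path: str | Path) -> None:
    """Write an image as 16-bit PNG/TIFF (lossless for integer rasters)."""
    path = Path(path)
    import imageio.v3 as iio

    arr = np.clip(image.pixels, 0.0, 1.0)
    iio.imwrite(path, (arr * 65535.0 + 0.5).astype(np.uint16))


def write_mask(mask: SegMask, path: str | Path) -> Path:
    """Write a binary mask losslessly (PNG as 0/255, NIfTI as 0/1).

    A ``{label}`` placeholder in ``path`` is formatted with the mask's
    vertebra label so multi-body outputs stay distinguishable on disk.
    Returns the path actually written.
    """
    path = Path(str(path).format(label=mask.label))
    try:
        if _infer_format(path) == "nifti":
            import nibabel as nib

            nib.save(nib.Nifti1Image(mask.pixels.astype(np.uint8), np.eye(4)), str(path))
        else:
            import imageio.v3 as iio

            iio.imwrite(path, (mask.pixels * 255).astype(np.uint8))
    except OSError as exc:
        raise IOError(f"cannot write mask to {path}") from exc
    return path


def read_mask(path: str | Path, label: int = 1) -> SegMask:
    """Read a mask written by :func:`write_mask` (any nonzero pixel -> 1)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"mask file not found: {path}")
    if _infer_format(path) == "nifti":
        import nibabel as nib

        arr = np.asarray(nib.load(str(path)).get_fdata())
        if arr.ndim == 3 and arr.shape[-1] == 1:
            arr = arr[..., 0]
    else:
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:
            arr = arr[..., 0]
    return SegMask((arr > 0).astype(np.uint8), label=label)
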