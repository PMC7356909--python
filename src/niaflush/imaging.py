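"""Photograph loading, region annotations and pixel-to-millimeter calibration.

A measurement is one photograph of the forearm with two manually marked
regions: area 1, the patch of skin treated with methyl nicotinate solution,
and area 2, an adjacent untreated patch serving as the reference for the
subject's baseline skin color.  A ruler visible in the frame, annotated as
two pixel coordinates with a known physical distance, converts pixel
geometry to millimeters so the flush surface can be reported in mm².

Annotations live in a JSON sidecar next to each image::

    {
      "subject": "S01", "group": "HC",
      "concentration_m": 0.01, "time_min": 5,
      "ruler": {"p1_xy": [370.0, 20.0], "p2_xy": [370.0, 120.0],
                "distance_mm": 10.0},
      "area1": {"polygon": [[30.5, 40.5], [90.5, 40.5], [90.5, 110.5],
                            [30.5, 110.5]]},
      "area2": {"mask": "photo_area2.png"}
    }

Polygon vertices are ``[x, y]`` pairs in pixel units (x = column,
y = row); a mask alternative references a single-channel 0/255 PNG of the
image's shape.  Pixel coordinates used in code are 0-based ``(row, col)``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path as FsPath
from typing import Any

import numpy as np
from matplotlib.path import Path as MplPath
from PIL import Image

from .color_models import SkinThresholds, skin_plausible
from .errors import (
    AnnotationError,
    EmptyAreaError,
    OverlappingAreasError,
    ShapeMismatchError,
    UnsupportedImageError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RulerAnnotation",
    "ScaleCalibration",
    "AnnotatedPhotograph",
    "rasterize_polygon",
    "load_photograph",
    "calibrate_scale",
    "region_area",
    "valid_pixels",
]


@dataclass(frozen=True)
class RulerAnnotation:
    """Two pixel coordinates on the ruler plus their physical distance.

    ``p1`` and ``p2`` are 0-based ``(row, col)`` positions; they may be
    sub-pixel (floats).  ``physical_distance_mm`` is the true distance
    between them on the ruler.
    """

    p1: tuple[float, float]
    p2: tuple[float, float]
    physical_distance_mm: float

    def __post_init__(self) -> None:
        if tuple(self.p1) == tuple(self.p2):
            raise AnnotationError("ruler endpoints must be distinct")
        if not (self.physical_distance_mm > 0):
            raise AnnotationError("ruler physical distance must be positive")


@dataclass(frozen=True)
class ScaleCalibration:
    """Image scale as millimeters per pixel."""

    mm_per_pixel: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mm_per_pixel) and self.mm_per_pixel > 0):
            raise AnnotationError("mm_per_pixel must be finite and positive")


@dataclass
class AnnotatedPhotograph:
    """An 8-bit RGB photograph with its two region masks and ruler.

    Invariants enforced on construction: masks match the image shape, the
    two areas are disjoint, and both are non-empty.
    """

    pixels: np.ndarray  # (H, W, 3) uint8
    area1_mask: np.ndarray  # (H, W) bool
    area2_mask: np.ndarray  # (H, W) bool
    ruler: RulerAnnotation
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[-1] != 3:
            raise UnsupportedImageError("image must be H x W x 3")
        if self.pixels.dtype != np.uint8:
            raise UnsupportedImageError(
                f"image must be 8-bit RGB, got dtype {self.pixels.dtype}"
            )
        self.area1_mask = np.asarray(self.area1_mask, dtype=bool)
        self.area2_mask = np.asarray(self.area2_mask, dtype=bool)
        shape = self.pixels.shape[:2]
        for name, mask in (("area1", self.area1_mask), ("area2", self.area2_mask)):
            if mask.shape != shape:
                raise ShapeMismatchError(
                    f"{name} mask shape {mask.shape} does not match image shape {shape}"
                )
            if not mask.any():
                raise EmptyAreaError(f"{name} mask is empty")
        if (self.area1_mask & self.area2_mask).any():
            raise OverlappingAreasError("area 1 and area 2 overlap")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def rasterize_polygon(polygon_xy: np.ndarray | list, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a simple polygon to a boolean mask at pixel centers.

    ``polygon_xy`` lists vertices as ``(x=col, y=row)`` pairs in pixel
    units; the pixel at ``(row, col)`` has its center at ``(x=col, y=row)``.
    A pixel belongs to the mask when its center lies inside the polygon
    (even-odd rule; polygons are assumed simple, i.e. non-self-intersecting,
    for which the even-odd and winding rules coincide).
    """
    poly = np.asarray(polygon_xy, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise AnnotationError("polygon must be a list of at least 3 [x, y] vertices")
    h, w = shape
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    centers = np.column_stack([cols.ravel(), rows.ravel()]).astype(float)
    # an open Path is implicitly closed by contains_points; closed=True
    # would instead consume the final vertex as the CLOSEPOLY marker
    inside = MplPath(poly).contains_points(centers)
    return inside.reshape(h, w)


def _load_mask_file(path: FsPath, shape: tuple[int, int]) -> np.ndarray:
    try:
        with Image.open(path) as img:
            arr = np.asarray(img.convert("L"))
    except (OSError, ValueError) as exc:
        raise AnnotationError(f"cannot read mask file {path}: {exc}") from exc
    if arr.shape != shape:
        raise ShapeMismatchError(
            f"mask {path} has shape {arr.shape}, image has shape {shape}"
        )
    return arr > 127


def _resolve_area(
    spec: Any, name: str, shape: tuple[int, int], base_dir: FsPath
) -> np.ndarray:
    if not isinstance(spec, dict):
        raise AnnotationError(f"{name} annotation must be an object")
    if "polygon" in spec:
        return rasterize_polygon(spec["polygon"], shape)
    if "mask" in spec:
        return _load_mask_file(base_dir / spec["mask"], shape)
    raise AnnotationError(f"{name} annotation needs a 'polygon' or 'mask' entry")


def _parse_ruler(spec: Any) -> RulerAnnotation:
    if not isinstance(spec, dict):
        raise AnnotationError("'ruler' annotation must be an object")
    try:
        x1, y1 = spec["p1_xy"]
        x2, y2 = spec["p2_xy"]
        dist = float(spec["distance_mm"])
    except (KeyError, TypeError, ValueError) as exc:
        raise AnnotationError(f"malformed ruler annotation: {exc}") from exc
    return RulerAnnotation(p1=(float(y1), float(x1)), p2=(float(y2), float(x2)),
                           physical_distance_mm=dist)


def load_photograph(image_path: str | FsPath, annotation_path: str | FsPath) -> AnnotatedPhotograph:
    """Load an image and its JSON annotation sidecar.

    Raises :class:`UnsupportedImageError` for images that are not 8-bit
    RGB(A), :class:`AnnotationError` for malformed sidecars, and the
    shape/overlap/empty validation errors from
    :class:`AnnotatedPhotograph`.
    """
    image_path = FsPath(image_path)
    annotation_path = FsPath(annotation_path)
    try:
        with Image.open(image_path) as img:
            if img.mode not in ("RGB", "RGBA"):
                raise UnsupportedImageError(
                    f"{image_path}: unsupported image mode {img.mode!r}; need 8-bit RGB"
                )
            pixels = np.asarray(img.convert("RGB"))
    except (OSError, ValueError) as exc:
        raise UnsupportedImageError(f"cannot read image {image_path}: {exc}") from exc

    try:
        annotation = json.loads(annotation_path.read_text())
    except OSError as exc:
        raise AnnotationError(f"cannot read annotation {annotation_path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"annotation {annotation_path} is not valid JSON: {exc}") from exc
    if "ruler" not in annotation or "area1" not in annotation or "area2" not in annotation:
        raise AnnotationError(
            f"annotation {annotation_path} must define 'ruler', 'area1' and 'area2'"
        )

    shape = pixels.shape[:2]
    base_dir = annotation_path.parent
    area1 = _resolve_area(annotation["area1"], "area1", shape, base_dir)
    area2 = _resolve_area(annotation["area2"], "area2", shape, base_dir)
    ruler = _parse_ruler(annotation["ruler"])
    metadata = {
        k: v for k, v in annotation.items() if k not in ("ruler", "area1", "area2")
    }
    return AnnotatedPhotograph(
        pixels=pixels, area1_mask=area1, area2_mask=area2, ruler=ruler, metadata=metadata
    )


def calibrate_scale(ruler: RulerAnnotation) -> ScaleCalibration:
    """Derive mm/pixel from the ruler's endpoints and physical distance."""
    dr = ruler.p1[0] - ruler.p2[0]
    dc = ruler.p1[1] - ruler.p2[1]
    pixel_distance = math.hypot(dr, dc)
    if pixel_distance == 0:
        raise AnnotationError("ruler endpoints coincide; cannot calibrate scale")
    return ScaleCalibration(mm_per_pixel=ruler.physical_distance_mm / pixel_distance)


def region_area(mask: np.ndarray, scale: ScaleCalibration) -> float:
    """Physical surface of a mask in mm² (pixel count × mm_per_pixel²)."""
    mask = np.asarray(mask, dtype=bool)
    count = int(mask.sum())
    if count == 0:
        raise EmptyAreaError("cannot measure the area of an empty mask")
    return count * scale.mm_per_pixel**2


def valid_pixels(
    photo: AnnotatedPhotograph,
    area_mask: np.ndarray,
    thresholds: SkinThresholds | None = None,
) -> np.ndarray:
    """Restrict a region mask to its skin-plausible pixels.

    Returns a boolean mask (subset of ``area_mask``) keeping only pixels
    whose chrominance passes ``thresholds``.  The number of excluded pixels
    is logged; an entirely excluded region yields an empty mask and a
    warning — callers that need pixels must check.
    """
    area_mask = np.asarray(area_mask, dtype=bool)
    if area_mask.shape != photo.shape:
        raise ShapeMismatchError(
            f"area mask shape {area_mask.shape} does not match image shape {photo.shape}"
        )
    ok = skin_plausible(photo.pixels, thresholds)
    result = area_mask & ok
    n_in, n_out = int(area_mask.sum()), int((area_mask & ~ok).sum())
    if n_out:
        logger.info("skin filter excluded %d of %d pixels", n_out, n_in)
    if n_in and not result.any():
        logger.warning("skin filter excluded every pixel of the region")
    return result
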