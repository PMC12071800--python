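"""Input/output formats: VIA polygon annotations, PNG masks, report CSV.

Binary masks are plain ``uint8`` numpy arrays with values in {0, 1},
indexed ``[row, col]`` with the row axis increasing downward — the usual
image convention. Polygon annotations carry vertices as ``(x, y)`` pairs
in pixel units, ``x`` = column, ``y`` = row.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from PIL import Image, UnidentifiedImageError
from shapely.geometry import Polygon as _ShPolygon
from shapely.validation import make_valid

from .errors import (
    DegeneratePolygonError,
    FormatError,
    OutOfFrameError,
    UnsupportedShapeError,
)

__all__ = [
    "PolygonAnnotation",
    "ReportRow",
    "parse_via_annotations",
    "polygon_to_mask",
    "rescale_to_height",
    "read_mask_png",
    "write_mask_png",
    "write_report_csv",
    "REPORT_HEADER",
]


@dataclass(frozen=True)
class PolygonAnnotation:
    """A closed polygon outlining the spine in one image.

    ``vertices`` is an ordered list of ``(x, y)`` pixel coordinates.
    """

    image_id: str
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) == 0:
            raise FormatError("annotation has no vertices")
        for x, y in self.vertices:
            if not (math.isfinite(x) and math.isfinite(y)) or x < 0 or y < 0:
                raise FormatError(f"vertex ({x}, {y}) is not finite and non-negative")


@dataclass
class ReportRow:
    """One line of the structured measurement report.

    ``record_type`` selects which of the remaining fields are populated:
    ``midpoint`` rows carry the grid geometry, ``upper``/``lower``/
    ``apex``/``tilted`` rows carry anatomical landmarks, and ``result``
    rows carry a Cobb angle plus its severity label.
    """

    record_type: str
    index: int | None = None
    y_px: float | None = None
    x_px: float | None = None
    x_left_px: float | None = None
    x_right_px: float | None = None
    angle_deg: float | None = None
    displacement_px: float | None = None
    label: str = ""

    _TYPES = ("midpoint", "upper", "lower", "apex", "tilted", "result")

    def __post_init__(self) -> None:
        if self.record_type not in self._TYPES:
            raise FormatError(f"unknown record_type {self.record_type!r}")
        if self.angle_deg is not None and not math.isfinite(self.angle_deg):
            raise FormatError("angle_deg must be finite when present")


REPORT_HEADER = [
    "record_type",
    "index",
    "y_px",
    "x_px",
    "x_left_px",
    "x_right_px",
    "angle_deg",
    "displacement_px",
    "label",
]


def parse_via_annotations(json_text: str) -> list[PolygonAnnotation]:
    """Parse a VIA 2.x project JSON into polygon annotations.

    Accepts both a full project export (with ``_via_img_metadata``) and
    the bare image-metadata mapping. One annotation is emitted per
    polygon (or polyline) region, vertex order preserved; images with no
    regions contribute nothing.
    """
    try:
        doc = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed VIA JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise FormatError("VIA JSON root must be an object")
    metadata = doc.get("_via_img_metadata", doc)

    annotations: list[PolygonAnnotation] = []
    for key, entry in metadata.items():
        if not isinstance(entry, dict) or "regions" not in entry:
            continue  # project bookkeeping keys (_via_settings, ...)
        image_id = entry.get("filename", key)
        for region in entry["regions"]:
            shape = region.get("shape_attributes", {})
            name = shape.get("name")
            if name not in ("polygon", "polyline"):
                raise UnsupportedShapeError(
                    f"region shape {name!r} in image {image_id!r} is not supported "
                    "(expected polygon or polyline)"
                )
            xs = shape.get("all_points_x")
            ys = shape.get("all_points_y")
            if xs is None or ys is None:
                raise FormatError(f"region in image {image_id!r} lacks coordinate arrays")
            if len(xs) != len(ys):
                raise FormatError(
                    f"image {image_id!r}: all_points_x has {len(xs)} entries "
                    f"but all_points_y has {len(ys)}"
                )
            annotations.append(
                PolygonAnnotation(
                    image_id=image_id,
                    vertices=tuple((float(x), float(y)) for x, y in zip(xs, ys)),
                )
            )
    return annotations


def polygon_to_mask(poly: PolygonAnnotation, height: int, width: int) -> np.ndarray:
    """Rasterize a polygon annotation into a binary mask.

    A pixel ``(r, c)`` is foreground iff its center ``(x=c, y=r)`` lies
    inside the polygon or on its boundary. Self-intersecting polygons
    are repaired (``make_valid``) before the containment test, so their
    fill follows the repaired geometry's covered area.
    """
    if height < 1 or width < 1:
        raise ValueError("mask dimensions must be >= 1")
    if len(poly.vertices) < 3:
        raise DegeneratePolygonError(
            f"polygon needs >= 3 vertices, got {len(poly.vertices)}"
        )
    for x, y in poly.vertices:
        if not (0 <= x <= width and 0 <= y <= height):
            raise OutOfFrameError(
                f"vertex ({x}, {y}) outside frame [0, {width}] x [0, {height}]"
            )
    geom = _ShPolygon(poly.vertices)
    if not geom.is_valid:
        geom = make_valid(geom)
    shapely.prepare(geom)

    mask = np.zeros((height, width), dtype=np.uint8)
    # Only pixel centers within the (padded) bounding box can be covered.
    minx, miny, maxx, maxy = geom.bounds
    c0, c1 = max(0, math.floor(minx)), min(width - 1, math.ceil(maxx))
    r0, r1 = max(0, math.floor(miny)), min(height - 1, math.ceil(maxy))
    if c1 < c0 or r1 < r0:
        return mask
    cols = np.arange(c0, c1 + 1)
    rows = np.arange(r0, r1 + 1)
    xx, yy = np.meshgrid(cols, rows)
    covered = shapely.covers(geom, shapely.points(xx.ravel(), yy.ravel()))
    mask[r0 : r1 + 1, c0 : c1 + 1] = covered.reshape(rows.size, cols.size)
    return mask


def rescale_to_height(mask: np.ndarray, target_height: int) -> np.ndarray:
    """Nearest-neighbour resample of a binary mask to a target height.

    Width scales proportionally (rounded, minimum 1) so aspect ratio is
    preserved up to rounding; binarity is preserved exactly, and a
    same-height call returns a bit-identical copy.
    """
    if target_height < 1:
        raise ValueError("target_height must be >= 1")
    h, w = mask.shape
    new_w = max(1, round(w * target_height / h))
    rows = np.floor((np.arange(target_height) + 0.5) * h / target_height).astype(int)
    cols = np.floor((np.arange(new_w) + 0.5) * w / new_w).astype(int)
    return np.ascontiguousarray(mask[rows][:, cols])


def read_mask_png(path: str | Path) -> np.ndarray:
    """Read an 8-bit grey or RGB PNG and binarize it.

    A pixel is foreground iff its luminance (ITU-R 601 weights for RGB)
    is >= 128.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        with Image.open(path) as img:
            if img.format != "PNG":
                raise FormatError(f"{path}: expected PNG, got {img.format}")
            grey = np.asarray(img.convert("L"))
    except UnidentifiedImageError as exc:
        raise FormatError(f"{path}: not a readable image") from exc
    return (grey >= 128).astype(np.uint8)


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit grey PNG (foreground 255)."""
    arr = (np.asarray(mask, dtype=np.uint8) > 0).astype(np.uint8) * 255
    Image.fromarray(arr, mode="L").save(Path(path), format="PNG")


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, str):
        return value
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return f"{float(value):.4f}"


def write_report_csv(rows: list[ReportRow], path: str | Path) -> None:
    """Write measurement report rows to CSV (numeric fields to 4 decimals)."""
    if not rows:
        raise ValueError("report must contain at least one row")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(REPORT_HEADER)
        for row in rows:
            writer.writerow(
                [
                    row.record_type,
                    _fmt(row.index),
                    _fmt(row.y_px),
                    _fmt(row.x_px),
                    _fmt(row.x_left_px),
                    _fmt(row.x_right_px),
                    _fmt(row.angle_deg),
                    _fmt(row.displacement_px),
                    row.label,
                ]
            )
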