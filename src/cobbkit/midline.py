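"""Spinal midline reconstruction from a binary mask.

The spine is taken to be the largest 8-connected foreground component.
Horizontal grid rows at a fixed interval cut the spine boundary in two
points each; the midpoint of each cut approximates the local vertebral
center, a natural cubic spline through the midpoints gives a continuous
midline x(y), and the spline's derivative gives the vertebral
inclination at each interior midpoint — the deviation of the local
spine axis from vertical, equal to the angle the perpendicular to the
curve makes with the horizontal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from skimage import measure

from .errors import (
    DegenerateInputError,
    InsufficientMidpointsError,
    NoSpineDetectedError,
)

__all__ = [
    "SpineRegion",
    "GridMidpoint",
    "Midline",
    "extract_spine_region",
    "compute_grid_midpoints",
    "fit_midline",
    "compute_inclinations",
]


@dataclass
class SpineRegion:
    """The selected spinal component of a mask.

    ``mask`` holds only this component; ``contour`` is its ordered,
    closed outer boundary as ``(row, col)`` coordinates (subpixel, from
    marching squares); ``area_px`` its pixel count.
    """

    mask: np.ndarray
    contour: np.ndarray
    area_px: int


@dataclass
class GridMidpoint:
    """Left/right boundary crossings of one grid row and their midpoint."""

    y: int
    x_left: int
    x_right: int
    x_mid: float
    inclination_deg: float | None = None

    def __post_init__(self) -> None:
        if self.x_left > self.x_right:
            raise ValueError("x_left must be <= x_right")


@dataclass
class Midline:
    """Spline midline x(y) through the grid midpoints.

    ``spline`` interpolates every midpoint exactly; ``rows``/``samples``
    hold x(y) at every integer row between the first and last midpoint.
    """

    midpoints: list[GridMidpoint]
    spline: CubicSpline
    rows: np.ndarray
    samples: np.ndarray

    @property
    def y_upper(self) -> int:
        return self.midpoints[0].y

    @property
    def y_lower(self) -> int:
        return self.midpoints[-1].y

    def interior(self) -> list[GridMidpoint]:
        """Midpoints excluding the upper and lower spine limits."""
        return self.midpoints[1:-1]


def extract_spine_region(mask: np.ndarray) -> SpineRegion:
    """Select the largest 8-connected foreground component as the spine.

    Ties on area are broken by the component whose topmost-then-leftmost
    pixel comes first in row-major order. The outer boundary contour is
    traced on the selected component alone.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not mask.any():
        raise NoSpineDetectedError("mask has no foreground pixels")
    labels, n = measure.label(mask > 0, connectivity=2, return_num=True)
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    best_area = areas.max()
    candidates = np.flatnonzero(areas == best_area)
    if candidates.size == 1:
        winner = candidates[0]
    else:
        flat = labels.ravel()
        first_idx = {lab: np.argmax(flat == lab) for lab in candidates}
        winner = min(candidates, key=lambda lab: first_idx[lab])
    component = (labels == winner).astype(np.uint8)
    padded = np.pad(component, 1)
    contours = measure.find_contours(padded, 0.5)
    contour = max(contours, key=len) - 1.0
    return SpineRegion(mask=component, contour=contour, area_px=int(best_area))


def compute_grid_midpoints(
    region: SpineRegion, grid_interval: int, min_midpoints: int = 5
) -> list[GridMidpoint]:
    """Sample boundary midpoints on grid rows spaced ``grid_interval`` apart.

    The grid is anchored at the region's topmost foreground row (making
    the result invariant to vertical placement in the frame) and the
    bottommost foreground row is appended as the final midpoint, so the
    first and last midpoints mark the upper and lower spine limits. At
    each grid row the leftmost and rightmost foreground columns of the
    region are the two boundary crossings; rows where the region is
    absent are skipped.
    """
    if grid_interval < 1:
        raise ValueError("grid_interval must be >= 1")
    comp = region.mask
    occupied = np.flatnonzero(comp.any(axis=1))
    y_top, y_bottom = int(occupied[0]), int(occupied[-1])
    grid_rows = list(range(y_top, y_bottom + 1, grid_interval))
    if grid_rows[-1] != y_bottom:
        grid_rows.append(y_bottom)

    midpoints: list[GridMidpoint] = []
    for y in grid_rows:
        cols = np.flatnonzero(comp[y])
        if cols.size == 0:
            continue
        x_left, x_right = int(cols[0]), int(cols[-1])
        midpoints.append(
            GridMidpoint(y=y, x_left=x_left, x_right=x_right, x_mid=(x_left + x_right) / 2.0)
        )
    if len(midpoints) < min_midpoints:
        raise InsufficientMidpointsError(
            f"only {len(midpoints)} grid midpoints (need >= {min_midpoints}); "
            f"try a grid interval smaller than {grid_interval}"
        )
    return midpoints


def fit_midline(midpoints: list[GridMidpoint]) -> Midline:
    """Fit a natural cubic interpolating spline x(y) through the midpoints."""
    if len(midpoints) < 4:
        raise InsufficientMidpointsError(
            f"need >= 4 midpoints for a cubic spline, got {len(midpoints)}"
        )
    ys = np.array([m.y for m in midpoints], dtype=float)
    xs = np.array([m.x_mid for m in midpoints], dtype=float)
    if np.any(np.diff(ys) <= 0):
        raise DegenerateInputError("midpoint rows must be strictly increasing")
    spline = CubicSpline(ys, xs, bc_type="natural")
    rows = np.arange(int(ys[0]), int(ys[-1]) + 1)
    return Midline(midpoints=list(midpoints), spline=spline, rows=rows, samples=spline(rows))


def compute_inclinations(midline: Midline) -> Midline:
    """Fill the vertebral inclination at each interior midpoint.

    The inclination is atan(dx/dy) of the spline at the midpoint's row,
    in degrees, signed positive when the midline moves rightward going
    down the image. The first and last midpoints (the spine limits) get
    no inclination.
    """
    deriv = midline.spline.derivative()
    for m in midline.interior():
        m.inclination_deg = float(np.degrees(np.arctan(deriv(float(m.y)))))
    midline.midpoints[0].inclination_deg = None
    midline.midpoints[-1].inclination_deg = None
    return midline
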