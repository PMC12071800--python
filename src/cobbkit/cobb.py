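"""Cobb-angle quantification and scoliosis severity classification.

Given the midline of a segmented spine, this module detects the apex
point(s) — the locations of greatest lateral displacement from a
vertical reference line through the upper spine limit — classifies the
curvature as simple (one apex, C-shaped) or complex (two apexes of
opposite sign, S-shaped), selects the most-tilted midpoints above and
below each apex, and computes the Cobb angle as the angle between the
perpendiculars erected at those two midpoints. Severity follows the
standard clinical scale: below 10° is a plain spinal curve, 10–20° mild,
20–40° moderate, and above 40° severe scoliosis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .config import PipelineConfig
from .errors import UnmeasurableCurveError
from .io_formats import rescale_to_height
from .midline import (
    GridMidpoint,
    Midline,
    SpineRegion,
    compute_grid_midpoints,
    compute_inclinations,
    extract_spine_region,
    fit_midline,
)

__all__ = [
    "Apex",
    "TiltedPair",
    "Severity",
    "CobbMeasurement",
    "AssessmentResult",
    "detect_apexes",
    "select_tilted_vertebrae",
    "cobb_angle",
    "classify_severity",
    "assess",
]

_TIE_EPS = 1e-9  # ties closer than this are treated as exact


@dataclass(frozen=True)
class Apex:
    """Point of maximal lateral displacement from the vertical reference.

    ``displacement`` is signed: negative when the apex lies left of the
    reference line, positive when right.
    """

    y: int
    x: float
    displacement: float


@dataclass(frozen=True)
class TiltedPair:
    """The most-tilted midpoints above (upper) and below (lower) an apex."""

    upper: GridMidpoint
    lower: GridMidpoint

    def __post_init__(self) -> None:
        if self.upper.y >= self.lower.y:
            raise ValueError("upper midpoint must lie above the lower one")
        if self.upper.inclination_deg is None or self.lower.inclination_deg is None:
            raise ValueError("tilted midpoints must carry inclinations")


class Severity(str, enum.Enum):
    SPINAL_CURVE = "spinal curve"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"

    @property
    def display(self) -> str:
        return {
            Severity.SPINAL_CURVE: "Spinal curve",
            Severity.MILD: "Mild scoliosis",
            Severity.MODERATE: "Moderate scoliosis",
            Severity.SEVERE: "Severe scoliosis",
        }[self]


@dataclass
class CobbMeasurement:
    """Complete curvature assessment of one spine."""

    curve_type: str  # "simple" | "complex"
    apexes: list[Apex]
    pairs: list[TiltedPair]
    angles_deg: list[float]
    severity: Severity
    reference_x: float


@dataclass
class AssessmentResult:
    """Measurement plus the intermediate landmarks, for reporting."""

    measurement: CobbMeasurement
    midline: Midline
    region: SpineRegion
    mask: np.ndarray  # the (possibly rescaled) mask actually measured


def detect_apexes(
    midline: Midline, apex_threshold: float
) -> tuple[list[Apex], str]:
    """Locate apex point(s) and classify the curve as simple or complex.

    The reference line is the vertical through the first (upper)
    midpoint. The displacement profile d(y) = x(y) − reference is
    sampled at every integer row of the midline; its local extrema with
    |d| >= ``apex_threshold`` are apex candidates. Candidates of both
    signs make the curve complex, returning the strongest candidate of
    each sign (upper first); otherwise the curve is simple with a single
    apex at the global maximum of |d| (even when below threshold).
    Exactly tied |d| maxima resolve to the median tied row, keeping a
    perfectly straight spine's apex central so midpoints exist on both
    sides of it.
    """
    ref = midline.midpoints[0].x_mid
    d = midline.samples - ref
    absd = np.abs(d)

    peaks, _ = find_peaks(absd)
    candidates = peaks[absd[peaks] >= apex_threshold]
    signs = set(np.sign(d[candidates]).astype(int)) - {0}

    def apex_at(i: int) -> Apex:
        y = int(midline.rows[i])
        return Apex(y=y, x=float(midline.samples[i]), displacement=float(d[i]))

    if signs == {-1, 1}:
        chosen = []
        for sign in (-1, 1):
            side = candidates[np.sign(d[candidates]) == sign]
            best = side[np.argmax(absd[side])]  # argmax returns first on ties
            chosen.append(best)
        chosen.sort()
        return [apex_at(i) for i in chosen], "complex"

    tied = np.flatnonzero(absd >= absd.max() - _TIE_EPS)
    i = int(tied[len(tied) // 2])
    return [apex_at(i)], "simple"


def _most_tilted(candidates: list[GridMidpoint], apex_y: int) -> GridMidpoint:
    """Midpoint of maximal |inclination|; ties go to the one nearest the apex."""
    best = max(
        candidates,
        key=lambda m: (abs(m.inclination_deg), -abs(m.y - apex_y)),
    )
    tied = [
        m
        for m in candidates
        if abs(abs(m.inclination_deg) - abs(best.inclination_deg)) <= _TIE_EPS
    ]
    return min(tied, key=lambda m: (abs(m.y - apex_y), m.y))


def _pair_for_segment(
    interior: list[GridMidpoint], apex: Apex, y_lo: float, y_hi: float
) -> TiltedPair:
    segment = [m for m in interior if y_lo <= m.y <= y_hi]
    above = [m for m in segment if m.y < apex.y]
    below = [m for m in segment if m.y > apex.y]
    if not above or not below:
        raise UnmeasurableCurveError(
            f"no interior midpoint {'above' if not above else 'below'} the apex at row {apex.y}"
        )
    return TiltedPair(upper=_most_tilted(above, apex.y), lower=_most_tilted(below, apex.y))


def select_tilted_vertebrae(
    midline: Midline, apexes: list[Apex], curve_type: str
) -> list[TiltedPair]:
    """Select the most-tilted midpoint above and below each apex.

    For a simple curve the whole midline is one segment. A complex curve
    is split between its two apexes at the row where the displacement
    profile changes sign (the crossing nearest the apexes' midpoint row
    if there are several, their y-midpoint if there is none); the simple
    rule is then applied within each segment.
    """
    interior = [m for m in midline.interior() if m.inclination_deg is not None]
    if curve_type == "simple":
        (apex,) = apexes
        return [_pair_for_segment(interior, apex, midline.y_upper, midline.y_lower)]

    upper_apex, lower_apex = apexes
    ref = midline.midpoints[0].x_mid
    between = np.arange(upper_apex.y, lower_apex.y + 1)
    d = midline.spline(between) - ref
    sign_change = np.flatnonzero(np.sign(d[:-1]) * np.sign(d[1:]) < 0)
    mid_row = (upper_apex.y + lower_apex.y) / 2.0
    if sign_change.size:
        # crossing nearest the apexes' midpoint; take the row with smaller |d|
        k = sign_change[np.argmin(np.abs(between[sign_change] - mid_row))]
        split = int(between[k] if abs(d[k]) <= abs(d[k + 1]) else between[k + 1])
    else:
        split = int(round(mid_row))
    return [
        _pair_for_segment(interior, upper_apex, midline.y_upper, split),
        _pair_for_segment(interior, lower_apex, split, midline.y_lower),
    ]


def cobb_angle(theta_upper: float, theta_lower: float) -> float:
    """Cobb angle (degrees) from the two endplate inclinations.

    The angle between the perpendiculars erected at the two most-tilted
    midpoints equals the angle between the endplate lines themselves,
    which is simply |θ_upper − θ_lower|; computing it algebraically
    avoids the degenerate parallel-line case of the intersection-point
    construction while giving the identical value.
    """
    if not (-90 < theta_upper < 90 and -90 < theta_lower < 90):
        raise ValueError("inclinations must lie in (-90, 90) degrees")
    return abs(theta_upper - theta_lower)


def classify_severity(
    angle_deg: float, bounds: tuple[float, float, float] = (10.0, 20.0, 40.0)
) -> Severity:
    """Map a Cobb angle to the clinical severity scale.

    Intervals are [0, 10) spinal curve, [10, 20) mild, [20, 40]
    moderate, and strictly above 40 severe: the upper bound is the only
    one stated without overlap in the clinical scale, the others are
    made lower-inclusive for determinism.
    """
    if angle_deg < 0:
        raise ValueError("Cobb angle must be non-negative")
    b1, b2, b3 = bounds
    if angle_deg < b1:
        return Severity.SPINAL_CURVE
    if angle_deg < b2:
        return Severity.MILD
    if angle_deg <= b3:
        return Severity.MODERATE
    return Severity.SEVERE


def assess(mask: np.ndarray, config: PipelineConfig | None = None) -> AssessmentResult:
    """Run the full measurement pipeline on a binary spine mask.

    Rescales to the configured height, selects the spinal region, builds
    the grid-midpoint midline, computes inclinations, detects apexes,
    selects the tilted vertebrae, and computes one Cobb angle per curve
    segment. For a complex curve the severity is assigned from the
    larger of the two angles.
    """
    if config is None:
        config = PipelineConfig()
    work = mask
    if config.rescale_height is not None:
        work = rescale_to_height(np.asarray(mask), config.rescale_height)
    region = extract_spine_region(work)
    midpoints = compute_grid_midpoints(
        region, config.grid_interval, min_midpoints=config.min_midpoints
    )
    midline = compute_inclinations(fit_midline(midpoints))
    apexes, curve_type = detect_apexes(midline, config.apex_threshold)
    pairs = select_tilted_vertebrae(midline, apexes, curve_type)
    angles = [cobb_angle(p.upper.inclination_deg, p.lower.inclination_deg) for p in pairs]
    severity = classify_severity(max(angles), config.severity_bounds)
    measurement = CobbMeasurement(
        curve_type=curve_type,
        apexes=apexes,
        pairs=pairs,
        angles_deg=angles,
        severity=severity,
        reference_x=midline.midpoints[0].x_mid,
    )
    return AssessmentResult(measurement=measurement, midline=midline, region=region, mask=work)
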