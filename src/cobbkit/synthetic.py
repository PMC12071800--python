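"""Synthetic spine phantoms with analytically known Cobb angles.

A phantom is a vertically oriented band of constant half-width around a
parametric midline x(y): a single-period cosine (C-shaped curve, one
apex, the canonical recovery fixture), a single-period sine (S-shaped
complex curve with one apex on each side), or a straight strip. For the
cosine form the inclination profile is θ(y) = atan(x'(y)) with extrema
±atan(2πA/λ) at the quarter-period rows, so the true Cobb angle is
2·atan(2πA/λ) in closed form — the ground truth every recovery test is
scored against. Optional per-row jitter of the left/right boundary
columns emulates segmentation-contour error.

The cosine (rather than sine) C-curve is canonical because its tilt
extrema sit strictly inside the spine, so excluding the upper and lower
limit midpoints from the inclination analysis does not clip them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SyntheticSpineSpec",
    "SyntheticTruth",
    "generate_spine_mask",
    "analytic_cobb",
    "fixture_suite",
]


@dataclass(frozen=True)
class SyntheticSpineSpec:
    """Parameters of one synthetic spine phantom.

    The spine occupies rows [y_top, y_top + wavelength] (one full period
    of the curve). ``amplitude`` and ``wavelength`` are in pixels at the
    image scale; ``half_width`` is half the band width; ``noise_sd`` is
    the standard deviation (px) of the per-row boundary jitter.
    """

    amplitude: float
    wavelength: float
    curve_form: str = "cosine_C"  # "cosine_C" | "sine_S" | "straight"
    image_height: int = 2000
    image_width: int = 600
    half_width: int = 60
    center_x: float = 300.0
    y_top: int = 400
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.curve_form not in ("cosine_C", "sine_S", "straight"):
            raise ValueError(f"unknown curve_form {self.curve_form!r}")
        if self.half_width < 3:
            raise ValueError("half_width must be >= 3")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    def midline_x(self, y: np.ndarray | float) -> np.ndarray | float:
        t = (np.asarray(y, dtype=float) - self.y_top) / self.wavelength
        if self.curve_form == "cosine_C":
            return self.center_x + self.amplitude * np.cos(2 * np.pi * t)
        if self.curve_form == "sine_S":
            return self.center_x + self.amplitude * np.sin(2 * np.pi * t)
        return self.center_x + np.zeros_like(t)


@dataclass(frozen=True)
class SyntheticTruth:
    """Closed-form ground truth of a phantom."""

    cobb_deg: float
    apex_rows: tuple[int, ...]
    tilt_extremum_rows: tuple[int, ...]
    curve_type: str  # "simple" | "complex"


def analytic_cobb(spec: SyntheticSpineSpec) -> float:
    """Ground-truth Cobb angle of a phantom, in degrees.

    cosine_C and straight have closed forms (2·atan(2πA/λ) and 0); the
    S-curve's overall value is computed numerically as max θ − min θ of
    the inclination profile over the interior, at 1-px steps.
    """
    if spec.curve_form == "straight" or spec.amplitude == 0:
        return 0.0
    if spec.curve_form == "cosine_C":
        return math.degrees(2 * math.atan(2 * math.pi * spec.amplitude / spec.wavelength))
    ys = np.arange(spec.y_top + 1, spec.y_top + spec.wavelength)
    t = (ys - spec.y_top) / spec.wavelength
    slope = spec.amplitude * (2 * np.pi / spec.wavelength) * np.cos(2 * np.pi * t)
    theta = np.degrees(np.arctan(slope))
    return float(theta.max() - theta.min())


def generate_spine_mask(spec: SyntheticSpineSpec) -> tuple[np.ndarray, SyntheticTruth]:
    """Rasterize a phantom into a binary mask and return its ground truth.

    Pixel (y, x) is foreground iff y lies in the spine's row range and
    |x − midline(y)| <= half_width. With ``noise_sd > 0`` each row's
    left and right boundary columns are independently shifted by
    rounded Gaussian noise (deterministic in ``seed``) and clamped so
    every row keeps at least 3 foreground pixels inside the frame.
    """
    lam = spec.wavelength
    y0, y1 = spec.y_top, int(round(spec.y_top + lam))
    if y0 < 0 or y1 > spec.image_height - 1:
        raise ValueError("spine rows exceed the frame height")
    ys = np.arange(y0, y1 + 1)
    xc = np.asarray(spec.midline_x(ys), dtype=float)
    left = np.ceil(xc - spec.half_width).astype(int)
    right = np.floor(xc + spec.half_width).astype(int)
    if left.min() < 0 or right.max() > spec.image_width - 1:
        raise ValueError("spine columns exceed the frame width (amplitude + half_width too large)")

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        left = left + np.rint(rng.normal(0, spec.noise_sd, ys.size)).astype(int)
        right = right + np.rint(rng.normal(0, spec.noise_sd, ys.size)).astype(int)
        # keep every row >= 3 px wide, centered where it was
        narrow = right - left < 2
        mid = ((left + right) // 2)[narrow]
        left[narrow] = mid - 1
        right[narrow] = mid + 1
        np.clip(left, 0, spec.image_width - 3, out=left)
        np.clip(right, left + 2, spec.image_width - 1, out=right)

    mask = np.zeros((spec.image_height, spec.image_width), dtype=np.uint8)
    for y, lo, hi in zip(ys, left, right):
        mask[y, lo : hi + 1] = 1

    if spec.curve_form == "cosine_C":
        truth = SyntheticTruth(
            cobb_deg=analytic_cobb(spec),
            apex_rows=(int(round(y0 + lam / 2)),),
            tilt_extremum_rows=(int(round(y0 + lam / 4)), int(round(y0 + 3 * lam / 4))),
            curve_type="simple",
        )
    elif spec.curve_form == "sine_S":
        truth = SyntheticTruth(
            cobb_deg=analytic_cobb(spec),
            apex_rows=(int(round(y0 + lam / 4)), int(round(y0 + 3 * lam / 4))),
            tilt_extremum_rows=(y0, int(round(y0 + lam / 2)), y1),
            curve_type="complex",
        )
    else:
        truth = SyntheticTruth(
            cobb_deg=0.0,
            apex_rows=(),
            tilt_extremum_rows=(),
            curve_type="simple",
        )
    return mask, truth


#: amplitude × wavelength grid of the clean C-curve recovery battery
RECOVERY_AMPLITUDES = (20, 40, 60, 80)
RECOVERY_WAVELENGTHS = (1000, 1200, 1600)


def fixture_suite(
    seed: int = 0,
) -> list[tuple[SyntheticSpineSpec, np.ndarray, SyntheticTruth]]:
    """Deterministic phantom battery used by the tests and docs.

    One straight strip, the 12 clean cosine C-curves over the amplitude
    × wavelength grid {20,40,60,80} × {1000,1200,1600}, one S-shaped
    complex case, and one noisy C-curve: 15 fixtures in all. The same
    seed always regenerates bit-identical masks.
    """
    specs: list[SyntheticSpineSpec] = []
    specs.append(
        SyntheticSpineSpec(amplitude=0, wavelength=1200, curve_form="straight",
                           y_top=(2000 - 1200) // 2, seed=seed)
    )
    for amp in RECOVERY_AMPLITUDES:
        for lam in RECOVERY_WAVELENGTHS:
            specs.append(
                SyntheticSpineSpec(amplitude=amp, wavelength=lam, curve_form="cosine_C",
                                   y_top=(2000 - lam) // 2, seed=seed)
            )
    specs.append(
        SyntheticSpineSpec(amplitude=50, wavelength=1200, curve_form="sine_S",
                           y_top=(2000 - 1200) // 2, seed=seed)
    )
    specs.append(
        SyntheticSpineSpec(amplitude=80, wavelength=1200, curve_form="cosine_C",
                           y_top=(2000 - 1200) // 2, noise_sd=2.0, seed=seed)
    )
    return [(spec, *generate_spine_mask(spec)) for spec in specs]
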