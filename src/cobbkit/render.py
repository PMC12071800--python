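"""Best-effort overlay rendering of a measurement onto an image.

The overlay mirrors the clinical review panel: the spine contour, the
grid midpoints and spline midline, the most-tilted vertebra lines in
red, and their perpendiculars (the Cobb construction lines) in green,
with the angle and severity stamped in a corner. The CSV report is the
canonical output; the PNG is for human inspection only and makes no
byte-exactness promises.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .cobb import AssessmentResult


def _endplate_segment(x: float, y: float, theta_deg: float, half_len: float):
    th = math.radians(theta_deg)
    dx, dy = math.cos(th) * half_len, math.sin(th) * half_len
    return (x - dx, y - dy, x + dx, y + dy)


def render_overlay(
    result: AssessmentResult,
    path: str | Path,
    background: np.ndarray | None = None,
) -> None:
    """Draw the measurement overlay and save it as a PNG.

    ``background`` may be a greyscale radiograph of the same shape as
    the measured mask; by default the mask itself is used.
    """
    mask = result.mask
    if background is not None and background.shape == mask.shape:
        base = np.asarray(background, dtype=np.uint8)
    else:
        base = (mask > 0).astype(np.uint8) * 160
    img = Image.fromarray(base, mode="L").convert("RGB")
    draw = ImageDraw.Draw(img)

    contour = result.region.contour
    for r, c in contour[:: max(1, len(contour) // 2000)]:
        draw.point((c, r), fill=(255, 220, 0))

    midline = result.midline
    pts = list(zip(midline.samples, midline.rows.astype(float)))
    draw.line(pts, fill=(60, 120, 255), width=2)
    for m in midline.midpoints:
        draw.ellipse((m.x_mid - 3, m.y - 3, m.x_mid + 3, m.y + 3), outline=(255, 255, 255))

    meas = result.measurement
    for apex in meas.apexes:
        draw.ellipse((apex.x - 5, apex.y - 5, apex.x + 5, apex.y + 5), outline=(255, 0, 255), width=2)
    for pair in meas.pairs:
        for m in (pair.upper, pair.lower):
            half_w = (m.x_right - m.x_left) / 2.0
            # red: the tilted vertebra (endplate) line, at the inclination angle
            draw.line(_endplate_segment(m.x_mid, m.y, -m.inclination_deg, half_w),
                      fill=(255, 0, 0), width=3)
            # green: its perpendicular, extended for the Cobb construction
            draw.line(_endplate_segment(m.x_mid, m.y, 90 - m.inclination_deg, half_w * 2.5),
                      fill=(0, 200, 0), width=2)

    angle_txt = " / ".join(f"{a:.1f} deg" for a in meas.angles_deg)
    draw.text((8, 8), f"Cobb: {angle_txt}  [{meas.severity.display}]", fill=(255, 255, 255))
    img.save(Path(path), format="PNG")
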