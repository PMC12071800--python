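# Methods

## The measurement model

`cobbkit` measures spinal curvature from a single-instance binary
segmentation of the spine on an AP radiograph. It deliberately does not
segment individual vertebrae: the working assumption is local vertebral
symmetry — at any height the midpoint between the left and right spine
boundary approximates the vertebral body centre, so the curve through
these midpoints is a faithful model of the spinal axis. The Cobb angle is
then a property of that curve: the inclination θ(y) = atan(x′(y)) of the
midline at a midpoint equals the angle of the local endplate
(perpendicular to the curve tangent) with the horizontal, and the angle
between the two extreme endplates above and below the apex is
|θ_upper − θ_lower|. This algebraic form is identical to the classical
construction that intersects the two perpendiculars, but has no
degenerate case when the endplates are parallel (angle 0).

The pipeline stages and their assumptions:

- **Height normalisation (default 2000 px).** All distances (grid
  interval, apex threshold) are calibrated at this scale; nearest-
  neighbour resampling preserves binarity exactly and is the identity
  when the input already has the target height. Width scales
  proportionally, so angles are preserved up to the rounding of one axis.
- **Largest-component selection.** Assumes the spine is the largest
  segmented object; smaller detections (artifacts, clavicles) are
  discarded. Ties are broken by the topmost-then-leftmost component pixel
  so the choice is deterministic.
- **Row-scan crossings.** At each grid row the leftmost and rightmost
  foreground columns of the selected component stand in for the two
  line–contour intersections. For a simple (vertically monotone) contour
  they are the same points; when a row crosses the contour more than
  twice the row-scan remains well defined where a geometric intersection
  rule would be ambiguous.
- **Grid anchoring.** The grid starts at the region's topmost row, not at
  image row 0, making the measurement invariant to where the spine sits
  in the frame; the bottommost row is always appended so the upper and
  lower spine limits are explicit landmarks.
- **Interpolating (not smoothing) spline with natural end conditions.**
  The midline passes exactly through every midpoint; a smoothing
  parameter would be an extra free parameter with no principled default.
  The natural boundary condition (x″ = 0 at the ends) concentrates its
  approximation error in the two outermost grid intervals — on the
  cosine phantom the dense-evaluation error is < 0.1 px in the interior
  but up to ~0.3 px in the end intervals. The end midpoints carry no
  inclination anyway, so this affects the measured angle only through
  the second and second-to-last midpoints, within the stated 2°
  recovery tolerance.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `rescale_height` | 2000 | px | normalised mask height; `None` disables resampling |
| `grid_interval` | 50 | px | spacing of the midpoint grid rows at the normalised scale; roughly one vertebral body height, so each grid row falls within one vertebra |
| `apex_threshold` | 20 | px | minimum lateral displacement for a local extremum to count as an apex candidate when deciding simple vs. complex curvature; suppresses rasterization wiggle near the reference line |
| `severity_bounds` | (10, 20, 40) | degrees | cut points of the clinical severity scale |
| `min_midpoints` | 5 | — | minimum grid midpoints; guarantees ≥ 3 interior inclinations, i.e. at least two tilt candidates plus an apex |

## Numerical and policy choices

- **Severity interval endpoints.** The clinical scale is printed with
  overlapping bounds (10–20, 20–40, >40). Only ">40°" is unambiguous, so
  the implementation uses [0,10), [10,20), [20,40], (40,∞): lower-
  inclusive everywhere, with 40° still moderate and severity changing
  strictly above it. The classifier is total and deterministic on
  [0, ∞).
- **Apex ties.** Displacement maxima tied to within 1e-9 px resolve to
  the median tied row. A strictly smallest-row rule would pin a
  perfectly straight spine's apex to the top end of the midline, where
  no interior midpoint exists above it and the measurement would fail;
  the median rule keeps the degenerate zero-curvature case measurable
  (angle 0) while being irrelevant for any real curve, where the
  maximum is unique.
- **Tilt ties** (equal |inclination|) resolve to the midpoint closest in
  y to the apex, then to the smaller row.
- **Complex-curve split.** Between the two apexes the midline is split at
  the row where the displacement changes sign (the crossing nearest the
  apexes' midpoint row if several), falling back to the y-midpoint when
  d(y) does not cross zero; each half is then measured as a simple
  curve. The severity of a complex curve is that of the larger of its
  two angles — the clinically conservative choice.
- **Rasterization rule.** Polygon annotations are rasterized by a
  pixel-center, boundary-inclusive containment test (a pixel is
  foreground iff its centre lies in the closed polygon). Self-
  intersecting polygons are repaired with `make_valid` before the test,
  so their fill is the repaired geometry's covered area.
- **PNG binarization.** Grey or RGB PNGs binarize at luminance ≥ 128
  (ITU-R 601 weights), a fixed documented cut for 8-bit inputs.
- **ICC form.** ICC(2,1) — two-way random effects, absolute agreement,
  single measurement — is the standard form for method-agreement studies
  with two raters; the CI uses the F-distribution with Satterthwaite
  degrees of freedom. The point estimate is checked against a
  from-first-principles ANOVA oracle (1e-9) and against `pingouin`'s
  ICC(A,1) in the test suite.
- **MAD.** The paired MAD is the median of the absolute paired
  differences |a_i − b_i|, the quantity tabulated in method-comparison
  reports; the classic one-sample MAD (median deviation from the median)
  is a different statistic and is provided separately as
  `one_sample_mad`.
- **Limits of agreement** use the conventional 1.96·SD multiplier with
  sample (n−1) standard deviations, appropriate at the small n of
  method-comparison studies.
- **AP definition.** "mAP (IoU = 0.5:0.95)" is implemented in the COCO
  style restricted to one class and one instance per image: per
  threshold, detections are ranked by confidence, matched greedily to
  their image's single ground truth, and AP is the all-point-
  interpolated area under the precision–recall curve; for a single image
  this reduces to (#thresholds passed)/10.

## The phantom generator

A phantom is a band of constant half-width (default 60 px) around a
parametric midline over one full period: cosine (C-curve), sine
(S-curve) or straight. For the cosine form the inclination profile
θ(t) = atan(−(2πA/λ)·sin(2πt/λ)) has its extrema ±atan(2πA/λ) at the
quarter-period rows, giving the closed-form Cobb angle 2·atan(2πA/λ)
with apex at the half-period row. The cosine (not sine) arc is the
canonical recovery fixture because its tilt extrema are interior to the
spine; a sine arc starting at a zero crossing would place them exactly
at the excluded upper/lower limit midpoints.

The noise model jitters each row's left and right boundary columns
independently by rounded Gaussian offsets (default SD 2 px), clamped so
every row keeps ≥ 3 foreground pixels — emulating segmentation-contour
error, the dominant failure mode of mask-based measurement. It does
not emulate: vertebral texture, ribs/pelvis confounders, mask dropout
(missing rows), or the narrow-bounding-box truncation a region-proposal
network can produce. Passing the recovery tests therefore demonstrates
the geometric correctness and noise tolerance of the measurement stage,
not the behaviour of any upstream segmentation network on real
radiographs.

Default phantom geometry: 2000 × 600 px frame (the normalised working
height), centre column 300, one period placed symmetrically about the
frame's vertical centre. The recovery battery spans amplitude
A ∈ {20, 40, 60, 80} px × wavelength λ ∈ {1000, 1200, 1600} px —
analytic Cobb angles from 9° to 53°, covering all four severity classes
at a realistic range of curve lengths.

## Measured behaviour (recomputed by tests and `scripts/acceptance.py`)

- Clean-phantom recovery: all 12 grid fixtures measured within 2° of the
  closed form, all classified simple, apex within one grid interval.
- Noise robustness: mean absolute Cobb error over 20 jittered A=80,
  λ=1200 phantoms ≤ 4° (individual seeds can exceed this; the
  interpolating spline passes through noisy midpoints and the
  max-|inclination| selection is biased toward noise peaks).
- Symmetry: mirroring a mask changes no angle by more than 1e-6°;
  horizontal background padding is likewise inert. Vertical padding is
  inert once the fixed-height resampling stage is bypassed
  (`rescale_height=None`) — with resampling enabled, padding changes
  the input height and hence the resampling grid, so exact invariance
  cannot hold at that stage.

## Known limitations

- Curves with more than two apexes (triple curves) are outside scope;
  the pipeline reports at most an upper and a lower angle.
- Vertebral rotation/torsion is not assessed; the model is purely
  2-D frontal-plane geometry.
- The row-scan crossing rule assumes an approximately vertical spine;
  a spine segmented at a large tilt (or a mask with long horizontal
  protrusions) can place midpoints off the anatomical axis.
- The overlay PNG is best-effort visualisation; only the CSV report is
  covered by determinism guarantees.
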