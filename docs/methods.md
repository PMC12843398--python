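# Methods

This note documents the models, parameters and numerical choices behind
`pesrnfl`, and what its synthetic phantoms do and do not establish about
behavior on real photographs.

## Coordinate and angle conventions

Retinal degree coordinates place the fovea at the origin, +x toward the
ONH (nasal, right eye) and +y toward superior retina. All directed angles
use the fundus convention: 0° at the nasal margin (3 o'clock of a right
eye), increasing clockwise when the image is viewed with superior retina
up, so 90° is inferior and 270° superior. Left eyes are mirrored
horizontally at load time; all downstream geometry is right-eye.

Eyes are compared in a canonical frame with the ONH center at
(15°, 2°): each eye is translated (fovea to origin), rotated by
`atan(2/15) − disc-fovea angle` and scaled by `√(15²+2²)/|fovea→ONH|`.
The transform is an exact similarity, so fitted ellipses stay ellipses
and directed angles shift by the rotation only.

## Trajectory model and reference map

Fiber paths follow the published power-law trajectory model in a modified
polar frame centered on the ONH, `φ(r) = φ₀ + b(r−r₀)^c` with r₀ = 4°,
where φ₀ is the angular position on the r₀ circle (0 nasal, positive
superior). The hemifield-specific coefficient functions (including the
published erratum) are:

- superior (60° < φ₀ < 180°): `b = exp(−1.9 + 3.9·tanh(−(φ₀−121)/14))`,
  `c = 1.9 + 1.4·tanh((φ₀−121)/14)`;
- inferior (−180° < φ₀ < −60°): `b = −exp(0.7 + 1.5·tanh(−(−φ₀−90)/25))`,
  `c = 1.0 + 0.5·tanh((−φ₀−90)/25)`;
- nasal (|φ₀| ≤ 60°): straight radial course (b = 0).

Traces stop where they would cross the horizontal raphe (|φ| > 180°).
Inside r₀ the model is undefined; because fibers physically converge on
the disc, traces are extended inward to near the disc margin as radial
stubs. Trajectory tangents are differentiated numerically along the trace
and validated against the closed-form derivative in the tests.

The reference map rasterizes the full fan (1° spacing in φ₀ by default)
onto a 3 px/° grid — coarse enough that adjacent traces are contiguous
after a 1-px nearest-source dilation, which is what makes ≥95% of retina
pixels (field-of-view circle minus the ONH interior) carry a defined
angle. The ten-region partition of the field (four peri-ONH quadrants,
four peripheral quadrants, a macular disk, a temporal raphe strip) is a
documented default — the original partition geometry is not recoverable —
and can be replaced by labeled polygons. Per region, the admissible
orientation window is the smallest wraparound-aware arc containing all
reference angles in the region, widened by a margin (default 5°); this
replaces the original data-driven window refinement, whose training
images are unavailable, while keeping the mechanism.

Near the fovea the model's papillomacular tangents deviate from the
fovea→ONH direction by up to ~25–30° (near-raphe trajectories curve
strongly there); they straighten to within 15° on the inner half of the
axis. The tests encode this measured behavior.

## Segmentation parameters

All defaults are expressed at a base scale of 32 px/° (1440-px-wide 45°
frame) and rescaled with the actual resolution:

| parameter | default | notes |
|---|---|---|
| ROI threshold | 0.05 | largest component + hole fill; exactly idempotent |
| median kernel | 3 px (5 px above 1500-px width) | ROI-restricted window |
| sigmoid gain / cutoff | 10 / 0.5 | monotone remap, then ROI min–max rescale |
| CLAHE tiles / clip limit | 8×8 / 0.01 | in-package implementation; single-tile limit is exact global histogram equalization |
| Frangi σ | {1,2,3,4} px · scale | β = 0.5; c = half max Hessian norm per scale |
| vessel polarity | dark tubes (λ₂ > 0) | vessels darker than background on green |
| min vessel component | 50 px · scale² | |
| MM window | 15 px · scale | flat windows map to 0 |
| min segment size | 20 px | |
| min elongation | 2.0 | axis ratio of pixel covariance; below it a component's orientation is treated as undefined and the component is dropped (suppresses isotropic noise blobs) |
| link radius | 2.5° | |
| tol (individual / group) | 25° / 35° | plus a bearing check: the step direction to the next member must agree with both members' orientations within the individual tolerance, which keeps chains from hopping between parallel fibers |
| Bezier order | 10 (≥ 11 markers) | chord-length parameterization; markers sorted outward-in |
| entrance refinement | 2000 samples + bisection | resolves crossings far below 0.01° |
| working raster | 2300×3500 px over x ∈ [−30°, 30°] | mapping stage |
| acceptance radius | 0.86° | disk around each 24-2 point |
| dilation | 1 px, nearest-source values | |

The linking tolerances and radius were fixed on phantoms (the source
method publishes none) and are exposed in the run configuration, as are
all of the above.

## Landmarks

The ONH is detected twice — (A) boundary of the top-percentile brightness
region, (B) closed half-maximum iso-contour around the brightest point —
and the contour with the higher mean gradient magnitude wins (ties go to
A). Five boundary points at equal arc length feed a direct least-squares
conic fit constrained to an ellipse (the numerically stable partitioned
formulation with constraint 4ac − b² = 1, computed on normalized
coordinates). The fovea is found on a background-flattened image (narrow
minus wide Gaussian, removing vignetting), restricted to plausible
eccentricity temporal to the ONH, again with an intensity-minimum method
and a ring-contour method arbitrated by contour sharpness. Covariates
outside the published population ranges are logged as warnings, not
errors.

## Statistics

The stepwise regression uses the Gaussian-likelihood AIC
`n·ln(RSS/n) + 2k` (AICc available behind a flag), adding at each step
the covariate with the largest AIC decrease, ties broken by the fixed
covariate order. The AIC-optimal term set is recorded separately from the
*reported* set, which keeps only terms significant at p < 0.001 in the
final OLS fit — the inclusion rule of the per-location tables. The
distinction matters: with five candidates, forward AIC alone admits a
spurious covariate in roughly 40–60% of pure-noise datasets, so the
significance filter is what makes the reported models conservative.
Covariates are standardized internally (selection and p-values are
unaffected); coefficients are reported on the original scale. Exact fits
(RSS ≈ 0) are guarded by an RSS floor, and no term is added once the
residual degrees of freedom would be exhausted.

Circular quantities use minimal signed differences in (−180°, 180°];
per-location sets spanning the 0°/360° boundary are unwrapped by
subtracting 360° from angles ≥ 180° when the spread exceeds 180°, and
flagged irreducible if it still does.

## Synthetic phantoms: what they emulate, and what they don't

A phantom renders, at 960×1440 (45° field) by default: radial vignetting
(strength 0.3 on a 0.55 background), a bright ONH ellipse (+0.25, soft
sigmoid edge) whose geometry comes from the sampled covariates, a dark
foveal Gaussian (−0.12, σ 0.7°), striations along 72 model trajectories
warped into the eye's geometry, four darker arcade-like vessels (width
0.35°, contrast 0.15), and Gaussian sensor noise (σ 0.01). Striations are
drawn as short interrupted streaks (dashes of 0.6° separated by 0.25°,
FWHM 0.12°, contrast 0.05) rather than unbroken ridges: real striations
present as fragmentary texture, and the pointwise-extraction stage
requires spatially separate segments. Optional raphe gaps emulate the
known difficulty of tracing near the temporal raphe (off by default).
Ocular covariates are truncated normals with the published means, SDs and
min/max bounds; the disc–fovea angle is recomputed as `atan(ONH_y/ONH_x)`
so the sampled geometry is internally consistent (this slightly narrows
its range relative to the published column, and asymmetric truncation
shifts the ONH_y mean up by ≈0.06°).

Ground truth (trajectories, per-pixel tangent map, landmark geometry) is
recorded before noise. The cohort generator produces covariate/response
tables with planted linear effects for the regression tests without
rendering images.

Phantoms deliberately omit: reddish color texture and choroidal
background structure, vessel branching and central reflexes, RNFL
defects and pathology, media opacity, off-center framing, and camera
color processing. Passing the phantom suite therefore demonstrates that
the pipeline recovers known geometry under the model's own assumptions —
correct windows, linking, curve fitting, mapping and statistics — not
that it attains any particular accuracy on clinical photographs.

## Problem sizes used by the test and reproduction runs

The end-to-end checks use ten phantoms at 960×1440 (about 1,400 pointwise
extractions and ~47 ten-marker bundles per phantom), three
canonical-geometry phantoms for the per-location mapping check, 100
replicates of n = 546 eyes for effect recovery and 200 replicates of
n = 500 for the null, and 10,000 eyes for the sampler check; unit tests
run on 480×720 phantoms and small arrays. These sizes are the package's
own defaults for a reproducible desk-scale run.

## Known limitations

- The windows derived from min/max reference angles are wide in regions
  mixing straight nasal and strongly curved fibers; the effective
  percentage is correspondingly permissive there.
- Bundle chains break at vessel crossings and in the crowded peridisc
  zone; only a minority of chains reach the ONH boundary, so per-image
  entrance-angle counts are small (the source method reports the same
  qualitative difficulty near the raphe and at bifurcations).
- The per-location mean angle is sensitive to which fibers happen to be
  sampled inside the 0.86° disk when local tangent spread is large
  (nasal-boundary discontinuity of the trajectory model, peridisc
  arcuates); agreement with truth is therefore asserted at the 80%-of-
  locations level, not pointwise.
- Landmark detection assumes a macula-centered frame with the ONH
  visibly brighter than its surround; tilted or pathological discs are
  out of scope.
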