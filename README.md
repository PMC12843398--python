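# pesrnfl

Automatic tracing of retinal nerve fiber layer (RNFL) bundles in color
fundus photographs, with structure–function mapping of the 24-2 visual
field and an analysis of how ocular geometry drives intersubject
variability in that mapping.

The package is aimed at people working on structure–function maps of the
eye: it turns a fundus photograph into a set of pointwise RNFL extractions
(local fiber orientation samples), assembles them into bundle curves that
enter the optic nerve head (ONH), and relates both to the locations of a
24-2 perimetry grid — the machinery needed to build personalized maps from
accessible imaging rather than manual tracing or OCT.

## Method

Segmentation runs in four stages:

1. **Preprocess** — isolate the circular field of view, median-denoise,
   and correct illumination with a sigmoid intensity remap on the green
   channel (left eyes are mirrored into right-eye orientation).
2. **Vessel suppression** — contrast-limited adaptive histogram
   equalization (CLAHE), then a multiscale Hessian (Frangi) vesselness
   filter. Per scale σ the vesselness of a dark tube is
   `V = exp(-R_B²/2β²)·(1-exp(-S²/2c²))` with blobness `R_B = λ₁/λ₂` and
   structureness `S = √(λ₁²+λ₂²)`; the binarized map is subtracted from
   the fiber map.
3. **Pointwise extraction** — maximum–minimum (MM) modulation
   `v' = (v-min_W)/(max_W-min_W)` over a sliding window, Otsu
   binarization, vessel subtraction, and per-component directed
   orientations θ ∈ [0°, 360°) (0° at the nasal margin, 3 o'clock of a
   right eye, clockwise; the sense points along the fiber toward the ONH).
4. **Bundle assembly** — extractions are filtered by the admissible
   angular window of their field region (windows derived from the
   nerve-fiber trajectory model `φ(r) = φ₀ + b(r-r₀)^c`, r₀ = 4°, traced
   at 1° steps), linked into chains by orientation continuity, fitted with
   10th-order Bezier curves (≥ 11 markers), and intersected with the
   fitted ONH ellipse to obtain entrance angles.

For mapping, each eye is normalized into a canonical frame (fovea at the
origin, ONH center at 15° eccentricity, 2° above the horizontal meridian)
and intersected with the 24-2 grid: angles within 0.86° of a test point
(twice the Goldmann size III stimulus diameter) are collected, superior and
inferior locations exchange assignments (the retina-to-field inversion),
and sets spanning the 0°/360° boundary are unwrapped before computing the
per-location mean, SD and 95% limit (2·SD). Per location, a forward
stepwise ordinary-least-squares regression selected by the Akaike
information criterion (AIC = n·ln(RSS/n) + 2k) relates the mean angle to
five ocular covariates — ONH_x, ONH_y, disc–fovea angle, ellipticity
ratio, ONH area — reporting predictors significant at p < 0.001.

Everything is testable without clinical data through a synthetic phantom
generator: fundus-like images with striations along the trajectory model,
vessels, an elliptical ONH, a dark fovea, vignetting and sensor noise,
with ocular geometry sampled from published population distributions and
full ground truth recorded.

## Worked example

```python
from pesrnfl import PhantomSpec, render_phantom, segment_image, score_phantom
from pesrnfl.pipeline import PipelineContext

ctx = PipelineContext.build()                  # reference map + windows
img, truth = render_phantom(PhantomSpec(seed=1))
result = segment_image(img, ctx)
print(f"extractions: {len(result.extractions)}")
print(f"effective:   {result.effective_pct:.1f}%")
print(f"bundles:     {len(result.bundles)}")
s = score_phantom(result, truth)
print(f"pointwise orientation MAE: {s.pointwise_mae_deg:.2f} deg")
print(f"ONH center error:          {s.onh_error_deg:.3f} deg")
```

prints

```
extractions: 1376
effective:   95.6%
bundles:     46
pointwise orientation MAE: 1.79 deg
ONH center error:          0.135 deg
```

`effective` is the fraction of pointwise extractions whose orientation
falls inside the admissible angular window of their region — the
method's primary quality score; the orientation MAE compares each
extraction's directed angle with the true fiber tangent at that position;
the ONH error is the distance between the fitted and true ellipse centers.

A command-line interface wraps the same functions:
`pes synth`, `pes segment`, `pes map`, `pes stats`, `pes eval`
(see `pes --help`).

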