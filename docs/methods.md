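# Methods

## Physical model

The pipeline treats the specimen as a thin, non-absorbing phase object:
a cell layer of geometric thickness *d*(x, y) and a single effective
("integral") refractive index *n*cell immersed in medium of index
*n*medium delays the transmitted wave by

    Δφ(x, y) = (2π/λ) (n_cell − n_medium) d(x, y)   [rad].

Three quantities derive from it:

* **Dry mass.** The refractive index of cytoplasm rises linearly with
  the mass concentration of dissolved dry matter (chiefly protein), with
  proportionality α (the refractive increment). Integrating phase over
  the covered area then measures the non-aqueous mass directly:
  `DM = λ/(2πα) Σᵢ Δφᵢ A_pixel`, independent of the water content.
* **Mean thickness.** `d̄ = λ Δφ̄ / (2π (n_cell − n_medium))`, the exact
  inverse of the phase relation, requiring a known n_cell.
* **Spherical-cell model.** A suspended, rounded-up cell has chord
  thickness `d(ρ) = 2√(r² − ρ²)`, giving
  `Δφ(ρ) = (4π/λ)(n_cell − n_medium)√(r² − ρ²)` with central maximum
  `(4π/λ)(n_cell − n_medium) r`. Because the footprint determines *r*
  and the amplitude determines n_cell, a least-squares fit of this model
  to a phase image decouples refractive index from thickness — the step
  that makes the layer-thickness retrieval above well-posed.

These relations force the frame-wise identity
`DM = (n_cell − n_medium) · S_c · d̄ / α`, which the code maintains
exactly and the tests check to machine precision.

## Parameters and defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| λ | 532 | nm | frequency-doubled Nd:YAG source |
| n_medium | 1.339 | — | buffered culture medium |
| α | 2×10⁻⁴ | m³/kg | standard protein refractive increment (≈0.2 mL/g) |
| pixel pitch | 0.5 (0.25 for single-cell fits) | µm | object-space sampling; camera pitch ÷ magnification |
| blob threshold | 0.5 | rad | minimum peak phase for a fittable cell |
| segmentation threshold | Otsu, floored at 3× robust noise SD | rad | reproducible; the floor keeps empty frames empty |
| cleanup | closing r=3 px; objects/holes < 50 µm² removed | | a Caco-2 cell footprint is ≫ 50 µm² |
| sideband window | raised cosine, radius 0.8×&#124;carrier&#124; | cycles/px | see "Numerical choices" |
| frame interval / duration | 30 min / 81 frames (40 h) | | standard long-term assay economics |

A note on α: values near 1.8–2.1×10⁻⁴ m³/kg are the consensus for
protein-dominated cytoplasm, and only a value in this range makes the
per-cell dry masses computed from measured volumes and indices come out
in the hundreds of picograms expected for epithelial cells. α is
configurable for non-standard media or chromophore-rich cells.

## Holographic reconstruction

Off-axis holograms are demodulated in one shot: multiply the intensity
by the conjugate carrier `exp(−2πi(fₓx + f_y y))`, low-pass filter
around the origin, and take the argument of the complex result. This is
mathematically equivalent in output to spatial-phase-shifting
reconstructions; it was chosen because it is standard, fast, and easy to
validate against planted fields. The carrier, if not supplied, is
located as the dominant off-origin spectral peak in the fx > 0
half-plane (a convention resolving the Hermitian ± ambiguity), refined
to sub-bin accuracy by parabolic interpolation; an image with no peak at
least 5× the median spectral magnitude raises an error rather than
returning noise.

**Window radius.** The low-pass is a raised cosine that reaches zero at
radius 0.8×|carrier|. A cutoff at half the carrier magnitude — the
textbook worst-case-safe choice — halves the usable bandwidth again
through the cosine taper and visibly clips the spectrum of a
cell-sized sphere (round-trip RMSE > 2 rad); 0.8 recovers planted
spheres to ≈0.03 rad RMSE while still vanishing before the
autocorrelation term, which for the flat-amplitude objects simulated
here is a spectral delta exactly one carrier magnitude away. For
holograms with strong amplitude structure the radius is configurable.

Unwrapping uses reliability-ordered 2-D unwrapping
(`skimage.restoration.unwrap_phase`); the contract is the round-trip
tolerance, not the algorithm. The unwrapped field is shifted so its
minimum (over a designated background region when given) is zero, and a
least-squares 2-D polynomial fitted on cell-free pixels removes residual
tilt/aberration so that Δφ ≈ 0 off the cells — a precondition of the
dry-mass and thickness formulas. All round-trip comparisons exclude a
configurable 8-pixel border where FFT periodicity artefacts live.

## Sphere fitting

Initialisation is deterministic: centre from the phase-weighted centroid
of the thresholded blob, radius from its equivalent-area circle, index
from the closed-form relation at the peak. The fit minimises
model−image residuals over the blob bounding box dilated by 25% (the
surrounding background pixels anchor the model's zero level) with
bounded trust-region least squares. Volume and dry mass are exact
functions of the fitted (r, n_cell), never refit. Population summaries
report mean ± SE (SD/√n) over successful fits; failures (no blob,
non-convergence) are logged and excluded, and a single-cell "population"
reports SE 0 with a warning.

## Segmentation and rates

The covered area is a threshold mask on the background-corrected phase
after Gaussian smoothing (σ = 1 px), closed with a 3-px disc and cleaned
of sub-50-µm² objects and holes. The automatic threshold is Otsu's value
on the non-negative histogram, floored at three robust (MAD-based) noise
standard deviations so a cell-free noisy frame yields an empty mask.
Pixel bookkeeping: indices are 0-based row-major, physical coordinates
are pixel centres, areas are pixel counts × pitch².

Rates are ordinary-least-squares slopes of the per-frame metric series;
when replicates are supplied they are averaged per time point on a
shared grid first and a single regression is run on the average. The
reported uncertainty is the regression standard error of that single
fit, not the between-replicate spread — a deliberate choice, documented
here because the two differ when replicate heterogeneity dominates.
Thickness slopes are reported in nm/min (they are a thousandth of the
µm-scale of the other metrics). Cell-number estimates divide the
dry-mass change relative to frame 0 by the mean single-cell dry mass of
the matching suspended-cell population, so n(0) = 0 and the series
counts cells added to the wound region.

## Synthetic data

The generator plants exactly the structure the analysis assumes, which
is what makes recovery tests sharp and is also its main limitation.

* **Suspended cells**: spherical phase profiles with radius and index
  drawn from truncated normals (radius > 1 µm, index > n_medium + 0.001)
  plus iid Gaussian phase noise (default SD 0.05 rad). The three
  condition presets use radii 7.2 ± 1.2, 9.1 ± 1.3 and 11.7 ± 1.3 µm and
  indices 1.3713, 1.3707 and 1.3678 (population SDs back-scaled from
  n = 89 standard errors).
* **Wound assays**: two plateaus of configurable thickness and index
  whose inner fronts advance linearly into a gap band while the layers
  thicken linearly — piecewise-linear dynamics, matching the nearly
  linear time courses the rate constants are meant to summarise. Fronts
  are symmetric linear ramps of width 4 µm by default: an epithelial
  sheet tapers toward its migration margin rather than ending in a
  vertical wall, and a zero-width step is not band-limited, so it cannot
  survive sideband demodulation. Because the ramp is symmetric, the
  closed-form per-frame truths (area, thickness, volume, mass inside the
  gap) based on the front-line positions remain exact. Optional
  sinusoidal front roughness (zero mean) models spatially heterogeneous
  growth; its amplitude is a free knob with no calibrated value.

Not emulated: organelle-scale phase texture, mitosis as discrete events,
spatially correlated noise, defocus, and cell-level motility. Passing
recovery tests therefore demonstrate that the measurement chain is
unbiased for layers that satisfy the homogeneous-index thin-object
model, not that the biological assumptions hold for any given cell line.

## Degenerate inputs and tie-breaks

Empty segmentation masks are valid observations (all metrics 0), but an
empty mask passed to the thickness/dry-mass primitives is an error —
the distinction is deliberate: a frame can legitimately show no cells,
whereas asking for the mean over nothing is a caller bug. n_cell ≤
n_medium is rejected wherever thickness would be inferred (zero
contrast makes it unidentifiable). Negative dry-mass changes pass
through the cell-number estimate with a warning (mass can genuinely
leave the region). Touching cells merge into one connected component;
no watershed splitting is claimed.

## Problem sizes

Round-trip and recovery tests run on 120–240 px grids with carriers
(1/6, 1/8) cycles/px chosen on FFT bins (grids divisible by 24), single
-cell fits on 128² images, population tests at n = 89 cells, and assay
recovery on an 81-frame, 1400×220 px time-lapse — sizes at which every
planted parameter is recovered well inside its stated tolerance and the
whole suite completes in well under a minute of compute.
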