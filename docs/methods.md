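# Methods

## The measurement problem

A smartphone microscope couples a single aspheric objective to the phone's
own camera lens; magnification is the ratio of their focal lengths and sits
near unity (roughly 0.5–1.5). Practical image quality is set by three
quantities this package measures:

1. **Magnification** per axis, from a periodic grid target of known period
   imaged onto a sensor of known pixel pitch:
   `M = period_px · pixel_pitch / known_period`.
2. **Resolution**, as the full width at half maximum (FWHM) of the point
   spread function (PSF), measured from the edge transitions of a
   USAF 1951 three-bar chart element.
3. **Sampling adequacy**: whether the sensor pitch places enough pixels
   across the PSF central peak to actually exploit that resolution.

Radial distortion (`k₁`), the Rayleigh prediction `0.61 λ / NA`, and a
Michelson-contrast resolvability check for filamentous phantoms complete
the picture.

## Edge-derivative PSF estimation

A chrome-on-glass chart presents effectively ideal step edges. The
intensity cross-section through a three-bar element (perpendicular to the
bars, through their centers) is a sequence of six edge spread functions
(ESF). Differentiating the profile yields the line spread function (LSF);
for a symmetric PSF the LSF is the PSF's 1-D profile. Each of the six
alternating-sign transitions is fitted with a Gaussian — a first
approximation to the Airy pattern — and the resolution is reported as the
mean ± SD of the six fitted FWHMs (`FWHM = 2√(2 ln 2) σ`).

Design choices:

* **No pre-smoothing** before differentiation. Smoothing would bias the
  LSF; noise is instead absorbed by the least-squares fit.
* **Differentiation** is by central finite differences (one-sided at the
  endpoints), on the same grid as the profile.
* **Discretization handling.** A central difference over spacing `h` is a
  box average of width `2h`, and each image sample carries the sensor's
  pixel aperture (a box of width `h`). Fitting a bare Gaussian to such data
  inflates σ by up to several percent at phone-sensor sampling
  (σ ≈ 0.8–1.4 px for the lenses of interest). Each peak is therefore
  modelled, by default, as the *exact central difference of a Gaussian
  ESF* — a difference of two Gaussian CDFs sharing one σ — and the pixel
  aperture is removed in quadrature, `σ² → σ² − pitch²/12`, when the
  profile comes from an image. Numerical validation against analytic edges
  shows residual bias below 0.2% across σ/pitch from 0.76 to 2.3. Both
  refinements can be disabled (`discrete=False`,
  `aperture_correction=False`) to recover the plain Gaussian fit.
* **Initialization and robustness.** Peak locations start at the
  alternating-sign extrema of the derivative exceeding 5 × a robust noise
  estimate (1.4826 × MAD of the derivative tails); widths start from each
  extremum's half-height width. The fit runs in two stages: first with a
  single σ shared by all peaks — physically motivated, since every
  transition samples the same PSF, and numerically well conditioned — then
  with per-peak σ free within 2.5× of the shared solution. The second
  stage preserves the per-transition width spread that the reported SD
  summarizes, while the staging prevents the classic degeneracy in which
  two overlapping opposite-sign Gaussians collapse onto one center with
  huge cancelling amplitudes. Amplitude signs are pinned to the detected
  edge directions. Convergence: relative tolerance 1e-8 on the residual
  norm, iteration cap 500.
* **Reporting plane.** Fitted widths are sensor-plane μm; the headline
  FWHM is converted to the *sample plane* (divided by M), because that is
  the plane in which resolution compares against real feature sizes (a
  6 μm hair, a cell). `plane="sensor"` switches the convention.

## Sampling rule

The Nyquist-style check counts sensor pixels across the PSF central peak:
`points_per_peak = 2 · FWHM_sample · M / pixel_pitch`, adequate when ≥ 7.
The support of the "central peak" is not standardized; this package defines
it as 2 × FWHM (the full central lobe of a Gaussian to good approximation)
and exposes the factor as a configurable constant
(`CENTRAL_PEAK_FWHM_FACTOR`). The 7-point requirement is likewise a
parameter.

## Grid calibration

Line centers are found on intensity projections (mean over a central band
perpendicular to the measurement axis) as midpoints of each trough's
interpolated half-prominence crossings — accurate to ~0.01 px even for
wide, flat-bottomed lines, where a parabola through the extremum is not.
The period is the mean of center-to-center spacings after discarding
spacings deviating more than 30% from the median (guards against clipped
half-lines at the border and missed lines); its uncertainty is the
standard error of the retained spacings. Magnification uses centers in the
central third of the field, where radial distortion bias is smallest; the
window grows symmetrically if it holds fewer than three lines.

Distortion is fitted as the one-coefficient Brown model
`r' = r (1 + k₁ r²)`, radius normalized by half the image diagonal
(corner ≈ 1), center fixed at the geometric image center, `k₁ > 0` =
pincushion. Grid intersections are detected by thresholding a smoothed
image, isolating horizontal and vertical line masks by morphological
opening with long thin elements, intersecting them, and refining each
crossing separably with the same half-crossing midpoint estimator.
Blobs touching the image border are discarded (their centroids are
clipped). A least-squares fit then adjusts `k₁`, the two lattice periods
and the lattice offset to the detected positions.

## The synthetic forward model

`SceneConfig` drives an analytic sample-plane target through, in order:
magnification onto the sensor grid, inverse-mapped Brown distortion, PSF
convolution, multiplicative vignetting `1 − v r²`, Poisson shot noise
(controlled by `photon_gain`) and additive Gaussian read noise, all from a
single integer seed (identical config ⇒ bit-identical image).

* Rendering supersamples each sensor pixel (default 4×) and the binary
  targets are anti-aliased *analytically* — each fine sample receives the
  fractional bar coverage of its footprint — so rendered edge positions
  are continuous at the sub-pixel level. (Without this, edge positions
  quantize to 1/oversample pixels, which aliases into a spurious ~0.002
  radial-distortion signal on a symmetric grid.)
* The Gaussian PSF uses `σ = FWHM / (2√(2 ln 2))` in sample-plane μm,
  scaled to sensor pixels by `M / pixel_pitch`; kernels are normalized to
  unit sum (energy conserving) and truncated at ±4σ; borders are
  edge-replicated. The Airy option builds its kernel from NA and λ with
  the first zero at `0.61 λ / NA`.
* Default conditions mirror the reference acquisition the package was
  developed around: a 500 μm-period grid (100 μm variant available), a
  1.2 μm sensor pitch, magnifications 0.5–1.5, PSF FWHM 2.3–9.2 μm.
  "SNR 50" in the validation suites means read-noise SD equal to 1/50 of
  the 0.9 bar-to-background intensity range, with shot noise off.
* The filament phantom (dark strips of width ~6 μm on a bright field)
  emulates fibrous samples such as insect-wing hairs; the validation
  suite spaces them 10 μm apart, at which a 3 μm-FWHM system resolves
  individual filaments (Michelson modulation ≈ 0.7) while a 9 μm system
  does not (< 0.1).

What the generator does **not** emulate: chromatic aberration, field
curvature, coma, defocus gradients, camera ISP processing (demosaicing,
sharpening, compression), illumination structure beyond the quadratic
vignette, and dust/texture. Passing round-trip tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
every artefact of real phone images; the estimators' contracts (profile
placement tolerance, robust noise floors, partial-report degradation) are
where that robustness lives.

## Problem sizes in the validation suites

The five-condition recovery suite pairs each reference lens with its
magnification and PSF width — (1.5, 2.3), (0.9, 2.9), (1.2, 3.2),
(0.5, 4.3), (0.7, 9.2) (M, FWHM μm) — at SNR 50 over 10 seeds. Grid images
are 360–440 px square with the 100 μm-period target (3–5 lines per axis);
resolution scenes render chart element 4-2 alone in a field just enclosing
its tile. These sizes leave the estimators' accuracy limited by the method,
not the field of view, while keeping the full suite around two minutes.

## Degenerate inputs and edge cases

* Fields smaller than two grid periods, or chart elements that do not fit,
  raise a degenerate-scene error; elements finer than one sensor pixel are
  skipped with a recorded warning.
* Fewer than three detected lines, or intersections covering less than
  60% of the field, raise an insufficient-structure error.
* `k₁ ≤ −1/3` over the field makes the radial map non-invertible and is
  rejected.
* A profile with no derivative extremum above the noise floor, or fewer
  extrema than requested peaks, raises a fit error with diagnostics.
* Missing grid image: `characterize_lens` degrades to a partial report
  with sensor-plane resolution and an explicit warning.
* RGB inputs are collapsed to the mean of channels before analysis.

## Known limitations

* The distortion model is single-coefficient and centered; decentering and
  tangential terms are out of scope.
* The Gaussian LSF model underestimates the side-lobe structure of a true
  Airy PSF; widths are comparable (the Gaussian is fitted to the central
  lobe), but no MTF curve is derived.
* `smallest_resolvable_element` and `feature_contrast` use Michelson
  modulation with a configurable threshold (default 0.1); thresholds near
  the noise floor make the verdict noise-sensitive.
* On real images the exact cross-section placement within an element
  affects the six fitted widths at the few-percent level; the reported SD
  partially reflects that.
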