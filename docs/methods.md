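# Methods

## Forward model

One exposure is modelled in three steps, in beam order (grid sits between the
source and the object):

1. **Grid shadow.** The mesh is an ideal binary crossed grid: wire bands of
   width `duty · pitch_px` along both axes, centred on integer multiples of
   the pitch, transmission `open_transmission` in open cells and
   `wire_transmission` under wire (single wire or crossing).  Pixels are
   rendered with exact fractional wire coverage, so sub-pixel wire widths do
   not alias; the spatial mean over whole periods is exactly
   `w + (o − w)(1 − d)²`.  Defaults (`pitch_px=8`, `duty=0.05`, `o=0.95`,
   `w=0.05`) give a mean transmission of 86.2 %, inside the 85–90 % range
   typical of the nickel meshes used for this kind of imaging.  Rotated
   meshes are supported via 3×3 supersampling; the default orientation is 0°.
2. **Scatter blur.** Small-angle scattering blurs the grid shadow with a
   unit-mass isotropic Gaussian whose variance is linear in the local gold
   concentration, σ²(x, y) = k·c(x, y).  The linear coupling is the simplest
   model consistent with scatter signal tracking tissue gold content, and it
   makes the demodulated scatter metric log-linear in concentration.  The
   spatially varying convolution is realised by linearly blending a bank of
   uniformly blurred grids at σ levels quantized to 0.1 px.  Each uniform
   blur is performed in the Fourier domain with the continuous transfer
   function exp(−2π²σ²|f|²): a truncated sampled spatial kernel aliases
   badly at σ ≈ 0.5 px (tens of percent error in first-harmonic damping at
   pitch 8), whereas the Fourier route is exact, periodic, and
   mass-preserving.
3. **Attenuation and noise.** The blurred shadow is scaled by
   `fluence · exp(−A(x, y))` (Beer–Lambert) and, when noise is enabled,
   replaced by a Poisson draw seeded from the acquisition seed.  All
   randomness flows from that one seed; (seed, config) → image is a pure
   function.  Detector read noise and PSF are not modelled.

Geometry (1.6 m source–detector, magnification 2 or 4) enters the 2-D model
only through the effective pitch at the detector; `pitch_px` is specified
directly in detector pixels and cone-beam divergence is ignored.

## Reconstruction

Demodulation crops half-open square windows of half-width 1/(2·pitch) around
the (0,0), (1,0) and (0,1) carriers, re-centres each at DC, and
inverse-transforms at full resolution; only envelope magnitudes are used
(phase/refraction is discarded).  Absorption is the log zero-order ratio;
the scatter metric is the log ratio-of-ratios of first-order to zero-order
envelopes, sample over reference.  The log form is preferred over
`1 − ratio` because Gaussian damping makes it exactly 2π²σ²f₀², linear in σ²
and additive along the beam.  Diagonal (1,1) harmonics are ignored — the
method reports exactly two scatter directions.  No apodization is applied to
the windows; the band layout is recorded in the reconstruction metadata.
`scatter_to_sigma` inverts the closed form, clipping negative (noise-driven)
metric values to zero with a warning; negative values are retained in the
images themselves.

A margin of one grid period at the image border is excluded from all
quantitative statistics (FFT wrap-around); `ReconstructionResult.margin_px`
and `interior()` implement this.  The reference must show first-harmonic
modulation (a degenerate, wire-less grid raises an error) and a strictly
positive zero-order envelope (flat-field check).

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| `pitch_px` | 8 | px | ≥ 4 keeps first harmonics below Nyquist; 8 leaves a clean window of half-width 1/16 cycles/px |
| `duty` | 0.05 | – | with `o=0.95`, `w=0.05` yields 86 % mean transmission and ~5 % carrier modulation |
| `scatter_coupling` k | 0.05 | px²·cm³/µg | no published value exists; chosen once so 18–26 µg/cm³ lesions give σ ≈ 0.95–1.14 px — measurable, and far below pitch/2 where harmonics vanish |
| `fluence` | 10⁴ (10⁵ for recovery studies) | photons/px | published work reports exposure times, not fluence; 10⁴ gives ~1 % per-pixel shot noise |
| σ quantization step | 0.1 | px | blending error in the scatter metric < 10⁻³ at these σ |
| window half-width | 1/(2·pitch) | cycles/px | adjacent bands touch but never overlap |

## What the synthetic data does and does not emulate

The generator reproduces the statistical structure the analysis relies on:
carrier harmonics of a crossed mesh, Beer–Lambert attenuation,
concentration-dependent isotropic Gaussian damping of the carriers, and
Poisson counting statistics.  It does **not** emulate polychromatic spectra,
cone-beam geometry, detector MTF/read noise, anisotropic or non-Gaussian
scattering, or anatomical texture.  Passing tests therefore demonstrate the
correctness of the demodulation and quantification chain under the stated
model, not performance on animal or clinical images — in particular the
published in-vivo enhancement magnitudes (factors ≈ 6–8 between modalities)
depend on unavailable image data and are only mirrored qualitatively
(scatter enhancement strictly exceeding absorption enhancement for a
pure-scatter lesion).

Pixel-sharp tissue boundaries deserve a note: a hard edge has a broadband
spectrum that leaks into the (weak, ~5 % of DC) carrier bands and produces
log-amplified ringing in the scatter images — the dark-field analogue of
edge artifacts in real systems.  Since real tissue boundaries are not sharp
at detector resolution, `make_mouse_phantom` accepts `edge_sigma_px` to
soften region edges (demo configuration: 2–3 px); quantitative
property checks use smooth (resolvable) phantoms.  With hard edges the
reconstruction still runs but ROI statistics near boundaries are
artifact-dominated.

## Numerical choices and degenerate inputs

- Row-major coordinates, origin at top-left, frequencies in cycles/pixel,
  FFT index 0 = DC; half-open pixel and window bounds everywhere.
- Carrier estimation searches the two spectral axes for the largest non-DC
  peak, requiring ≥ 5× the spectral median; ties break toward larger
  magnitude, then lower frequency.
- `duty = 0` is accepted as the documented no-grid degenerate case (useful
  for null tests); reconstruction refuses it with a "no first-harmonic"
  error.
- σ exceeding the pitch triggers a warning (carrier fully damped, scatter
  unrecoverable) rather than an error.
- Sample SD (ddof = 1) is used for ROI statistics; published ± values are
  treated as SDs and propagate in quadrature on the relative scale in ratio
  tables.
- Display rounding matches common reporting practice — ratios to 2 decimals,
  enhancement factors to the nearest integer — with full precision retained
  internally.
- Integrated optical density is the background-subtracted sum
  Σ (I − t) over pixels I > t: the standard densitometric definition that
  responds to both stained area and brightness.
- Organ biodistribution factors with a zero-mean organ report infinity
  rather than raising.

## Problem sizes

Property checks run on 256² rasters (512² for the closed-form agreement
sweep), with the Monte-Carlo noise check at 64² × 100 seeds — sizes at which
every quantity of interest is already converged to well inside its
tolerance.  The full test suite and the acceptance script each complete in
seconds on one CPU.

## Known limitations

- The scatter coupling k is a modelling choice, not a measured constant;
  absolute σ values are only meaningful relative to the configured coupling.
- Isotropic blur means the horizontal and vertical scatter channels are
  statistically identical in simulation; directional contrast from oriented
  microstructure is out of scope.
- The demodulated images are low-pass limited to 1/(2·pitch) — the method's
  inherent resolution loss is accepted, not corrected.
- Flat-field normalization uses a single reference exposure; source drift
  between exposures is not modelled or corrected.
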