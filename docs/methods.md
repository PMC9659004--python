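# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic scenes do and do not emulate, and the
numerical decisions a user extending the package should know about.

## Image formation model (synthetic scenes)

Spots are rendered as integrated 2-D Gaussians: the flux landing in a
pixel is the product of error-function differences across the pixel edges,
so the total rendered flux equals the planted flux exactly on any grid
(point-sampling a Gaussian does not have this property). Pixel centres sit
at integer coordinates, origin at the top-left pixel centre; positions are
carried in µm and converted with `pixel_size`.

The camera model is the minimal chain needed to stress background
subtraction: expected photons per pixel (background level + optional
linear ramp + spots) → Poisson shot noise → linear gain → constant offset
→ Gaussian read noise. Defaults: 0.1 µm/px, PSF σ = 1.0 px (a
high-NA/green-emission scale at 100 nm pixels), 100 photons per
fluorophore, 50 photons/px background, gain 1 count/photon, offset 100
counts, read noise 2 counts. Real instruments rarely report gain and
offset, so every scene records its optics in the truth metadata.
Deliberately not modelled: 3-D PSFs, photobleaching, spectral
bleed-through, chromatic shifts, sample drift. Passing tests on these
scenes therefore demonstrates correctness of the measurement arithmetic
and estimator bias/variance under shot + read noise — not robustness to
optical artefacts absent from the generator.

Motion models: active transport is a straight line at speed v (random
heading); normal diffusion a Gaussian walk with per-axis step variance
2·D·dt; subdiffusion fractional Brownian motion with Hurst H < 0.5
(per-axis MSD = 2·D·t^2H, exact fGn covariance via Cholesky); confinement
a Brownian walk radially reflected inside a disc of radius L. Localisation
error is i.i.d. Gaussian on the observed (not true) positions. Each scene
derives per-object RNG streams from one seed, so identical seeds give
byte-identical outputs.

## Concentric-ROI fluorometry

A spot's intensity is the raw integrated density of an 8-px-diameter disc
minus the annulus (8–10 px) mean scaled to the inner-disc pixel area.
Pixel membership: a pixel belongs to a disc if its centre lies within
d/2 of the (sub-pixel) centroid — brute-force checkable, and the areas in
the correction formula are counted from the actual masks. Flat backgrounds
cancel exactly; a locally linear ramp cancels to first order. The two
diameters are taken at face value in detector pixels regardless of pixel
size and are exposed as parameters. Spots whose outer disc is clipped by
the border are flagged invalid; spots whose outer disc overlaps a
neighbour's inner disc are flagged crowded and excluded from calibration
cohorts. Negative corrected intensities are kept (clipping biases cohort
means upward) but counted in the output.

With PSF σ = 1 px, the 4-px inner radius captures >99.9% of a spot's
flux and the annulus carries <0.04% of it, so the measurement recovers
planted fluxes to ~0.1%; at σ ≳ 1.3 px, tail leakage into the annulus
costs ~2–3% — a systematic any user with a wider PSF should check with
the generator before trusting absolute counts.

## Detection

Scale-normalised Laplacian-of-Gaussian (σ = d/2√2 for an expected
diameter d, response ×σ²), local maxima above a quality threshold with a
minimum separation of d/2, optional 3×3 median pre-filter, and sub-pixel
refinement by separable quadratic interpolation (offsets clipped to
±0.5 px). Default d = 5 px at 0.1 µm/px with threshold 30 counts; on the
default optics this detects 24-mer standards (2400 counts) with zero
misses in practice while rejecting background maxima.

## Calibration and motor arithmetic

The standard curve is a through-origin least-squares fit to the
per-species mean intensities (s = Σxȳ/Σx²), matching how such curves are
plotted; a `per_spot` flag fits pooled spot values instead. R² is the
uncentred through-origin version. Molecules = intensity/slope; complexes =
molecules/2; the expression-correction factor is the ratio of cohort mean
intensities (reference/tagged; not medians, not a mean of ratios); the
corrected cohort mean applies that factor to the rounded cohort mean
before rounding to an integer — reported integers (139, 320) assume the
rounded means (65, 115), and `use_rounded_mean=False` exposes the
unrounded path. All molecule counts are invariant to rescaling every
intensity by a common factor.

## Geometry

Surface area uses the Thomsen approximation with p = 1.6075 (exact for
spheres, verified within 1.2% of a quadrature surface integral for axis
ratios to 3:1; the quadrature is available as `method="quadrature"`).
Motor density is the floor of area per complex — floor, not round, is
deliberate: 405037/320 = 1265.7 and the reported density convention
truncates. Note that for the virion dimensions used in the worked
examples (350×280×200 and 440×380×260 nm), Thomsen gives 238 418 and
404 683 nm²; the exact elliptic-integral areas are 238 337 and
404 510 nm².

## Tracking and motion-state segmentation

Linking solves per-frame-pair optimal assignment (Hungarian) on squared
displacement with a hard 0.8 µm radius, then a gap-closing pass joins
fragment ends to starts across ≤5 missing frames within a linearly
gap-scaled radius (0.8 µm × (missing+1)); gap frames are linearly
interpolated and flagged so MSD fits can drop them. This mirrors the
"simple LAP" structure (two passes, no global spatio-temporal optimum).
Tracks with net displacement ≤1 µm are discarded before classification.

Classification computes, per point, the log-log MSD exponent α over lags
1..⌊window/3⌋ inside a sliding 15-frame window (1.5 s at 10 Hz) plus the
window straightness (net/path). Thresholds: active if α ≥ 1.5 and
straightness ≥ 0.6; confined if α ≤ 0.4; subdiffusive if 0.4 < α < 0.9;
otherwise normal diffusion; segments shorter than 5 frames are absorbed
into their longer neighbour. Two numerical refinements matter:

1. **Noise floor.** Observed MSD = true MSD + 4σ² for localisation
   precision σ. At D ~ 0.01–0.02 µm²/s, dt = 0.1 s and σ = 30 nm the
   floor rivals the lag-1 MSD and drags α of genuine diffusion below the
   sub-diffusion boundary. When σ is known (simulations; or estimated
   from immobilised spots), pass `localization_sd` and 4σ² is subtracted
   before the fit.
2. **Estimator bias and segment refinement.** The mean of log windowed
   MSD is biased by ψ(ν/2) − ln(ν/2) for the effective χ² dof
   ν ≈ 2·(m/ℓ) at lag ℓ with m displacements; uncorrected, a 15-frame
   window yields α ≈ 0.93 ± 0.3 for pure diffusion — half of it below
   0.9. The fit subtracts this bias, and after the per-point pass each
   merged segment is re-classified from features over its whole span,
   iterating to stability; adjacent non-active segments with conflicting
   labels are joined when their union's own features confirm one of the
   two labels. Active segments never take part in that agglomeration, so
   active/diffusive alternation survives. On well-separated regimes
   (v = 0.6 µm/s vs D = 0.02 µm²/s vs L = 0.2 µm, 20 nm noise) pooled
   per-point accuracy across 20 seeds is ~96%; distinguishing
   sub-diffusion from normal diffusion at 15-frame resolution remains
   intrinsically noisy.

Active velocity is net displacement / duration (robust to noise-inflated
path length) and is exactly unbiased on noise-free ballistic tracks. The
motile count applies the >3 µm net displacement rule within the first
60 s of a track.

## Kymographs and run extraction

Kymographs resample each frame along the path at pixel_size arclength
steps, averaging `line_width_px` bilinear samples across the local
normal. Quantitative runs are not traced in kymograph image space:
detections are projected onto each microtubule (perpendicular distance
≤0.3 µm) to give along-path traces, and runs are maximal stretches where
the 3-frame-smoothed speed exceeds 0.1 µm/s for ≥3 s. Velocity is the
least-squares slope over the stretch with the smoothing half-width
trimmed from both ends (otherwise parked boundary frames deflate the
slope by ~2%); run length is the net |Δs|; a virion parking at the tip
ends its run at arrival and the stationary tail is excluded. Direction
comes from the slope sign against the microtubule's polarity (unknown
polarity → "unknown"); end fate is `reached_end` within 0.5 µm of the
targeted tip, `not_discernible` when censored by the movie end, else
`not_reached`. The motility rate divides motile-run counts by imaging
minutes × summed microtubule millimetres. The manual "constant-velocity
segment" criterion these defaults operationalise is inherently
judgement-based; all thresholds are exposed in the config.

## Peripheral spread

The cell mask splits into a peripheral band (Euclidean distance ≤5 µm
from the boundary, via distance transform on a zero-padded mask so
border-touching cells erode correctly) and an interior (strictly
farther); spots count by pixel lookup at their rounded position, with a
3×3 snap for raster edge effects. Counts are conserved exactly and the
peripheral percentage is monotone in band width. A band wider than the
inradius empties the interior with a warning, not an error.

## Workflows, sizes and determinism

`run_motor_counting` simulates 24/60/120/180-mer standards (50
spots/species), virion cohorts of 84 (IMV) and 121 (IEV) at 130/230
planted molecules with 50% copy-number CV, and antibody cohorts of 100
with planted 2.14×/2.78× fold-differences; at these study-scale ns the
fold estimate alone has ~7% s.e., so cohort-level sampling scatter
dominates pipeline bias (which is <1%). `run_motility` uses one field of
20 runs at N(0.66, 0.14²) µm/s plus 40 in-cell tracks alternating 3 s
active (0.61 µm/s) and 3 s diffusive (0.01 µm²/s) segments at 10 Hz with
20 nm localisation noise. Recovery tests use 200 runs / 100 tracks /
cohorts of 1000 where a tolerance is meant to probe bias rather than
sampling noise. Every workflow derives all randomness from one seed
(per-object substreams via `SeedSequence.spawn`) and writes a manifest
(parameters, seed, version) with each report; reports are timestamp-free
so identical seeds reproduce identical bytes.

## Known limitations

- The classifier is threshold-based, not probabilistic; no HMM/Bayesian
  state inference, no 3-D tracking.
- Molecule counts assume full fluorophore maturation and accessibility;
  no correction for either.
- Microtubule paths are supplied or generated, never segmented from a
  tubulin channel; cell masks are inputs, never segmented from images.
- Channels are assumed registered; no chromatic or drift correction.
- Ellipsoid areas are approximations (see Geometry) and virions are
  treated as perfect tri-axial ellipsoids.
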