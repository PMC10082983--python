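# Methods

## Cardiac time base

Frames are grouped into cardiac cycles by externally supplied boundary
indices (in the acquisition protocol these come from the pulse-oximetry
audio track; extracting them is out of scope). Within cycle *c* of
*n<sub>c</sub>* frames, frame *i* (1-based) gets nominal time
*t = i/n<sub>c</sub> + c − 1*, so each cycle occupies (c−1, c] and the last
frame of a cycle lands exactly on the integer — which is also where the
drift-spline knots sit. Per-cycle normalization absorbs heart-rate
variability across cycles (e.g. 102/102/103 frames over three cycles).
Cycle fractions convert to seconds by the mean cardiac cycle time
(0.852743 s for the reference acquisition). Reported arithmetic follows a
six-decimal-place rounding convention (`round_6dp`), off by default for
internal computation.

## Harmonic regression

The per-pixel design is: intercept, *t*, truncated-linear terms (t−k)₊ at
every whole-cycle knot interior to the span, and cosine/sine pairs for
harmonics 1..K of the cardiac fundamental. Two conventions deserve note:

- **Fundamental frequency.** The basis is cos(2πnt), sin(2πnt): with *t*
  in cycle fractions the first harmonic must have period one cardiac
  cycle. A `basis="pi"` switch is retained for a period-two fundamental,
  but nothing downstream uses it.
- **Intercept.** The Fourier mean term and the spline intercept are
  collinear; a single intercept is carried and reported as a0 (b0 ≡ 0).

Errors are a stationary AR(1) process on the frame index. Estimation uses
the exact whitening transform (first observation scaled by √(1−ρ²), later
rows differenced by ρ), giving GLS coefficient solutions by QR least
squares at each candidate ρ. ρ maximizes the restricted (REML) profile
log-likelihood over (−0.99, 0.99) by bounded scalar search (tolerance
1e−6); REML is preferred to ML for the correlation parameter because it
accounts for the eight estimated regression coefficients. Unit tests pin
the profile against a dense-matrix oracle (explicit Toeplitz covariance,
exhaustive ρ grid) and against `statsmodels` GLS at fixed ρ.

Model order is compared by AIC computed from the **full ML** likelihood
with parameter count = coefficients + 2 (ρ, σᵤ); REML likelihoods are not
comparable across different fixed-effect structures. With genuine two-
harmonic content AIC selects order 2 in ~80–90 % of replicates, so K = 2
is the pipeline default and orders above 4 are not offered.

Derived summaries use only the periodic component (the spline models
artifact, not pulse — so amplitude and trough are invariant to drift and
intercept): HRWa is its peak-to-trough range over one cycle and
time-to-trough its argmin on [0, 1), both located on a 4096-point grid
with bounded local refinement (ties broken toward smaller *t*).

Degenerate inputs never abort a stack run: constant or exactly
model-consistent (noiseless) series take an OLS fast path with ρ = 0 and a
`perfect_fit`/`degenerate` flag, and a fitted wave whose amplitude is at
numerical-noise scale relative to the data (≤ 1e−10 of the RMS intensity)
is reported as amplitude 0 with an undefined trough.

## Pulse mapping

Pixels are fitted independently (no spatial smoothing; an optional k×k
neighborhood mean pre-filter exists but defaults off). Coordinates are
0-based (row, col), row 0 at the top. Color input is reduced to the green
channel at read time. Outputs are full-precision CSV maps plus a QC code
map; per-pixel failures are flagged, not raised. Identical inputs and
configuration give bit-identical outputs.

## Velocimetry

Spatial calibration assumes a 1.65 mm optic-disc diameter; distance is the
geodesic (polyline) arc length of a user-supplied vessel path. Transit
time is distal minus proximal site time; a non-positive value is returned
with a direction warning rather than absolute-valued. Site times average
three wall points (nasal/central/temporal; count configurable) after
unwrapping each point to within half a cycle of the site's first value, so
sites straddling the cycle boundary (0.995 vs 0.005) stay coherent; the
between-site difference is likewise taken modulo one cycle with
representative in (−0.5, 0.5].

Two estimators are provided:

1. **Two-site transit chain** — the direct analogue of the clinical
   measurement. Its precision is set by per-pixel trough phase noise: at
   SNR 5 with AR(1) ρ = 0.5 over 307 frames the trough standard error is
   ≈ 0.009 cycles (≈ 0.008 s) per pixel, so three-point site means give a
   transit-time error of ≈ 6 ms — adequate for slow waves but a ~20 %
   single-run error for a 40 mm/s wave crossing 1.1 mm.
2. **Path-profile regression** (`pwv_from_path_profile`) — under constant
   propagation speed the trough time is linear in arc length, so the OLS
   slope of trough time (s) on arc position (mm) over every mapped vessel
   pixel is 1/PWV. Pooling ~600 pixels reduces the error to a few percent
   at the same SNR; this is the headline estimate of the recovery
   experiments. Both are always reported side by side.

`resolution_limits` encodes the sampling constraints of any frame-based
velocimeter: the frame period is the minimum resolvable time scale and the
spatial window divided by it bounds the measurable velocity (143.6 mm/s
for a 1.197 mm field at 120 FPS; 112.5/237.5/15.25 mm/s for 4.5/9.5/0.61 mm
windows at 25 FPS).

## Synthetic data

The generator emulates the statistical structure the model assumes, with
ground truth for every map: pixel intensity = baseline + global
piecewise-linear drift + A(s)·w(t − τ) + AR(1) noise, where w is a
two-harmonic unit-peak-to-trough waveform with its trough at t = 0 (so the
trough map equals the delay field), τ = arc·mm_per_pixel / PWV converted
to cycle fractions, and the noise is independent across pixels. SNR is
defined as A over the stationary noise SD σᵤ/√(1−ρ²).

Defaults mirror the reference acquisition: three cycles of 102/102/103
frames at 120 FPS, cycle time 0.852743 s, 0.01 mm/pixel, a ~1.2 mm
straight venous segment (the longest path the imaged field plausibly
offers), HRWa 10 intensity units, ρ = 0.5, σᵤ chosen for SNR 5, PWV
22 mm/s. Recovery experiments place sites at 5 %/95 % of the arc.

What the generator does **not** emulate — vessel reflectance and
illumination structure, saccadic/registration residuals beyond smooth
drift, spatially correlated noise, waveform shape changes along the vessel
— bounds what passing tests show: they validate the estimation machinery
under the model's assumptions, not robustness to real-video artifacts.

## Problem sizes and tolerances

Tests and the acceptance script run at the acquisition's native series
length (307 frames; 300 for replicate studies) but on compact images
(vessel segments of a few hundred pixels) and 50-replicate batches, which
pilot runs showed are ample to resolve every tolerance asserted: noiseless
map round-trips at 1e−6 (amplitude) and the trough-grid resolution;
seeded PWV recovery within 15 % for 10/22/40 mm/s at SNR 5; mean ρ
recovery within ±0.1 for ρ ∈ {0, 0.5, 0.8}; REML argmax within 0.01 of
the exhaustive grid oracle; AIC order-2 majority. Integer TIFF export
clips and rounds; internal arithmetic is unclipped float64.
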