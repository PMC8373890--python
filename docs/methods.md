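# Methods

`pomscan` maps particulate organic matter (POM) in hyperspectral
VisNIR/SWIR images of undisturbed soil-core profile faces.  This note
documents the models behind each stage, the synthetic study conditions
used for validation, and the numerical and design choices that were
genuinely open.

## Reflectance calibration

A push-broom line scanner records one across-track line at a time while
the core translates beneath the camera.  Because lamp illumination is
not uniform along the scan, object reflectance is computed per line
against a white reference panel recorded in the same scan:

ρ_obj(l, s, b) = L_obj(l, s, b) / L_ref(l, b) · ρ_ref(b)

with L_ref(l, b) the mean panel radiance over the panel's across-track
samples in line l.  Any gain multiplying object and panel radiance
jointly cancels exactly; the test suite asserts this invariance to
machine precision.  When the panel is imaged separately with a
different line count, its per-band mean is broadcast to all object
lines (the per-line correction is then unavailable; this mirrors how a
separately scanned panel is actually used).  Panel reflectance defaults
to 0.99, typical of a certified Spectralon panel.  Reflectance is never
clipped: facets brighter than the panel legitimately exceed 1.

Dark current is assumed already removed by the camera software; the
pipeline takes dark-corrected radiance as input.

## Binning and band masking

Averaging n pixels improves the signal-to-noise ratio by √n.
`bin_spatial` averages non-overlapping factor×factor blocks and drops
incomplete trailing blocks, so every output pixel is a true n-pixel
mean — padding would break the √n property at the edges.
`bin_spectral` averages contiguous source bands falling in consecutive
half-open intervals of the target width, with the new band center at
the mean of the member centers.  Band masking removes ranges rendered
unusable by sensor artefacts (in practice the SWIR above 2300 nm);
masking and spectral binning are checked to interact consistently with
downstream band selection.

## Endmember libraries

Reference spectra come from a laboratory point spectrometer on a 1 nm
grid (350–2500 nm, 2151 bands), smoothed with a three-band sliding mean
and resampled onto the camera wavelength grid.  Resampling uses boxcar
band-averaging over the half-open interval [c − w/2, c + w/2) with w
the target band width (FWHM if known, else the local center spacing).
A boxcar response was chosen over a Gaussian because it requires no
instrument FWHM model and is exactly the "mean of neighbouring bands"
convention already used for spectral binning; for the smooth spectra
involved the difference is far below the sensor noise level.  An
interval containing no source sample is an error, not an
extrapolation.

## Constrained unmixing

Each pixel spectrum s is modelled as a convex combination of an organic
endmember (oPOM — occluded particulate organic matter, the purest
organic fraction) and a mineral endmember (MinRest — the mineral
residue after POM removal):

s = a·E_om + (1 − a)·E_min + e,  a ∈ [0, 1].

The estimate minimises ‖E·a − s‖₂ under both non-negativity and
sum-to-one (fully constrained least squares).  Both constraints are
imposed — rather than non-negativity alone — so that a is directly
interpretable as the areal fraction of the pixel covered by organic
matter.  For two endmembers the solution is closed-form: project s onto
the segment between the endmember vectors,

â = clamp(⟨s − E_min, E_om − E_min⟩ / ‖E_om − E_min‖², 0, 1),

which the tests verify against an exhaustive 10⁻⁴-step simplex search,
including out-of-simplex inputs that clamp to a vertex.  The abundance
estimate is invariant to any common positive scaling of spectrum and
endmembers, and strictly increasing in the true mixing fraction.

Only five diagnostic bands enter the fit — 2012, 2108, 2228 and
2276 nm, sitting in cellulose/lignin absorption features of organic
matter, and 2204 nm at the Al-OH lattice absorption of phyllosilicate
clays as the mineral identifier.  Restricting to bands with a physical
interpretation avoids the overfitting that full-spectrum regression
invites when millions of image spectra are available.  Targets map to
the nearest grid band within a 6 nm tolerance (about one SWIR band),
ties breaking toward the lower wavelength.  No shade endmember is used:
illumination variation is handled by the per-line calibration, which is
the physically correct place for it.

With σ the reflectance noise per band, the propagated least-squares
error of â is σ/‖E_om − E_min‖; the acceptance suite checks recovery
RMSE against the deliberately loose bound 3σ√5/‖E_om − E_min‖ over 20
noise seeds (clamping at the simplex boundary only reduces the error).

## Particle segmentation

Pixels with organic abundance strictly above τ = 0.05 are foreground;
maximal connected components are SpecPOM particles and their pixel
count is the particle size.  8-connectivity is the default so thin
diagonal root traces remain single particles; 4-connectivity is
available.  Labels are numbered in raster-scan order of each
component's first pixel, which makes the per-block assignment rule —
a particle belongs to the ROI block containing its first pixel —
deterministic and easy to verify against an independent flood-fill
implementation.  First-pixel assignment was preferred over centroid
assignment because it is exact under relabeling and particles
straddling a block edge are rare at the block sizes used.

## Profile and ROI statistics

The imaged face carries a grid of ROI blocks (2 columns × 5 depth rows,
nominally 4.5 × 6 cm, depth rows 0–6 … 24–30 cm) matching the blocks
cut out for physical fractionation.  Per block: SpecPOM % = 100 × mean
abundance, and SpecPOM size = mean size of the particles anchored in
the block.  Line-wise cover sums the per-line mean abundance over
non-overlapping 10-line windows; per-line cover is normalised by the
sample count so profiles from cameras of different widths are
comparable, and windows do not overlap so consecutive values are
independent.  A trailing partial window is reported with its actual
line count.

Pearson correlations between image metrics and lab fraction variables
(bulk, fPOM, oPOM, soPOM, MinRest, and the derived sums POM and
fPOM+oPOM, all in mg C g⁻¹ soil) are computed for all blocks and per
grazing treatment, optionally with listed outlier blocks excluded
before correlating.  A correlation on fewer than three records or on a
constant variable is flagged undefined (NaN plus an explicit `defined`
column) rather than silently reported as 0.  Significance testing
(ANOVA, post-hoc letters) is deliberately out of scope; the per-block
table is emitted for external statistics packages.

## Synthetic study conditions

The generator emulates the full acquisition so every stage can be
tested against known truth.

* **Spectra.**  MinRest: convex rising visible continuum to a SWIR
  plateau near 0.45, water dips at 1450 and 1930 nm, and a sharp
  2206 nm Al-OH dip (depth 0.07, σ 13 nm).  oPOM: darker visible part,
  a broad trough across 2000–2300 nm (depth 0.085, σ 120 nm) and no
  2206 nm feature.  Seeded low-frequency perturbations (amplitude
  ≤ 0.006) individualise libraries without breaking any feature
  constraint; the 5-band endmember matrix has condition number ≈ 40.
* **Particles.**  Filled rotated ellipses, axis ratio 2–6, pixel count
  drawn uniformly in 8–40 and realised exactly (pixels ranked by
  elliptical distance), interior abundance 1 and a one-pixel rim at
  0.5 to model sub-pixel mixing at particle edges.  Line-wise Poisson
  counts with intensity ∝ exp(−depth/decay); defaults (3 particles
  cm⁻² at the surface, 8 cm e-folding) give a few-percent top-layer
  cover declining to near zero at 30 cm, matching the magnitude and
  ordering seen in grassland Chernozem profiles.  Particle centers keep
  a margin from the image edge so no particle is clipped and the
  configured size range is met exactly.
* **Rendering.**  Reflectance = a·oPOM + (1 − a)·MinRest + N(0, σ)
  (σ = 0.005 by default, floored at 0 as a dark-corrected sensor
  records no negative radiance); radiance multiplies by a sinusoidal
  per-line gain (default amplitude 10%) and a 3000 K lamp curve; the
  panel is rendered noise-free under identical illumination.  The
  noiseless forward model is exactly invertible by
  calibration + unmixing, which the tests assert to 10⁻⁶.
* **Fraction tables.**  Per block, POM stock = α·(true block abundance)
  + N(0, σ_f), floored at 0, split 0.55/0.25/0.20 into
  fPOM/oPOM/soPOM (free > occluded ≈ small, the stock ordering of
  grassland topsoils); MinRest follows an independent depth-declining
  trend and bulk C is the sum.  The coupling strength has the closed
  form r = α·s_a/√(α²s_a² + σ_f²), inverted by `noise_sigma_for_r` to
  design studies at a target correlation.

What the generator does **not** emulate: bidirectional reflectance and
shadowing, aggregate microstructure, spatially correlated noise,
nonlinear (intimate) mixing, and moisture gradients.  Passing tests
therefore demonstrate the correctness of the algorithms under the
linear mixing model, not field-scale accuracy on real cores.

## Problem sizes

Test and acceptance scenes are 120×60 to 240×120 pixels with the 279
bands of the 5.5 nm SWIR grid, 20 noise seeds for recovery bounds, 500
random masks for the segmentation oracle, and 200 simulated 40-block
studies per coupling level — sizes chosen so the whole validation suite
re-runs in well under a minute per stage while keeping Monte-Carlo
standard errors an order of magnitude below the tolerances checked.
The analysis drivers use 600×120-pixel profiles (30 cm at 0.5 mm
along-track after the generator, 2×2-binned to 300×60) as a
representative desk-scale study.

Correlation-recovery simulations redraw the block-abundance design each
seed (blocks ~ N(0.10, 0.012), truncated at 0) so that (abundance,
stock) are jointly random and the Fisher-z dispersion 1/√(n−3) applies;
the abundance spread keeps the floor-at-zero active in well under 0.1%
of blocks even at the weakest coupling tested (r = 0.3), so the design
correlation is not distorted.

## Numerical choices and degenerate inputs

* Cube storage: float32 for reflectance, uint16 for raw counts;
  all in-memory arithmetic in float64.  Wavelengths are printed with
  full `repr` precision so grids survive text round trips bit-exactly.
* Band-selection ties break toward the lower wavelength; argmin over a
  sorted grid implements this without a special case.
* Identical endmembers raise a degeneracy error in the pixel solver;
  a condition number above 10⁶ raises at matrix construction.
* τ thresholding uses strict inequality ("> 5%" read literally), so an
  abundance of exactly 0.05 is background.
* Empty ROI blocks report mean size 0 and count 0; empty resampling
  intervals and all-masked cubes raise errors naming the offender.

## Known limitations

Two-endmember unmixing cannot separate POM from other dark phases
(char, Mn oxides) and the five-band choice is calibrated to
phyllosilicate-dominated mineralogy; both would need re-validation on
other soil types.  Particles touching each other merge into one
segmented component (no watershed splitting), biasing size upward at
high cover — the generator reproduces this behaviour, and the
segmentation tests only assert count equality for scenes whose truth
particles are verifiably disjoint.  Correlations against fraction
tables assume one ROI grid per profile face; registration between
imagery and physically cut blocks is idealised as exact.
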