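# Methods

`autoidif` derives an image-derived arterial input function (IDIF) for
dynamic PET from a co-acquired time-of-flight MR angiography (TOF-MRA)
volume, without arterial blood sampling in the loop.  This note documents
the model behind each stage, the parameters that matter, what the synthetic
phantoms emulate, and the numerical choices made where the design was open.

## Pipeline model

**Vessel enhancement.**  For every voxel of the MRA volume, the intensities
inside a sphere of radius *r* (mm, evaluated in world coordinates so the
anisotropic 0.5 × 0.5 × 0.7 mm voxels are handled correctly) are treated as
point masses and the inertia tensor about their centroid is formed.  With
eigenvalues λ₁ ≤ λ₂ ≤ λ₃, the prolateness

p = (λ₂ − λ₁) / (λ₁ + λ₂ + λ₃)

is a scale-invariant measure of how cigar-shaped the local intensity
distribution is: an ideal line has (0, ℓ, ℓ) and p = 0.5, a ball has p = 0,
and 0 ≤ p ≤ 0.5 always.  Sensitivity to a vessel of radius ρ requires
r > ρ (a sphere inside a homogeneous tube sees a uniform ball), so p is
computed for radii from twice the smallest voxel dimension up to 8 mm in
1 mm steps and combined per voxel as P = √Σᵢ p(rᵢ)² — the root sum of
squares suppresses single-scale noise.  The spacing of the scale ladder is
not critical (sensitivity is flat above ~4 mm); the 1 mm step is exposed in
the configuration.  Spheres truncate at the volume border, which equals
exact zero padding.  The MRA volume multiplied voxel-wise by P is the
enhanced volume.

The whole-volume map is computed from ten moment images (mass, first and
second moments) obtained by FFT correlation with spherical kernels; the
per-voxel 3 × 3 eigenproblems use the closed-form trigonometric solution.
Both routes — FFT map and direct per-voxel summation — are cross-checked in
the tests to 1e-10.

**Segmentation.**  The enhanced volume is thresholded at the first local
minimum above zero of its 100-bin intensity histogram (after a width-3
moving average; width 1 restores the raw rule).  This adapts to the
arbitrary intensity scale of MR data: background, bone and soft tissue form
the low mode, vessels the high mode, and the first minimum falls in the gap
between them.  Foreground voxels (strictly above threshold) are grouped
into 26-connected components; the two largest are the straight segments of
the bilateral carotid arteries.  Because the injection catheter retains
tracer and would bias the IDIF, only the artery *contralateral* to it is
used: the PET maximum-over-time image is treated as a mass distribution,
and the candidate whose center of gravity lies farther from the PET center
of gravity is kept.  Ties (symmetric scenes) break deterministically to the
larger cluster with a logged warning.

**Alignment.**  The MRA precedes the PET acquisition by many minutes, so
the animal may have sunk or rolled slightly.  Arteries run axially and the
dominant error is in-plane, so alignment is two-dimensional per axial
slice: the in-plane mask center of gravity is compared with the position of
the PET maximum within 20 mm of it (the window keeps catheter or rete
hot-spots from capturing the estimate).  The PET slice is pre-smoothed with
a 1.4 mm Gaussian — the blurred artery cross-section is symmetric, so
smoothing suppresses noise jitter of the argmax without moving the peak —
and the maximum is refined to sub-voxel precision with a three-point
parabola per axis.  The per-slice shifts are smoothed by independent
unweighted quadratic fits dx(z), dy(z) over slice position; slices within
~one FWHM (7 mm) of the mask's axial ends are excluded from the fit because
axial blur near the tube ends mixes in-plane positions and biases the
per-slice maximum.  The fitted shift is applied slice-by-slice with
cubic-spline interpolation, clamped to [0, 1] so interpolation ringing
cannot leak into partial-volume coefficients.  Finally the (fractional)
mask is projected to the PET grid by exact axis-separable box overlap: each
PET voxel receives the volume-weighted mean of the mask over its footprint,
preserving total arterial volume to well under 1%.

**PSF calibration.**  The scanner point-spread function is modeled as an
isotropic Gaussian parameterized by its FWHM and measured once from a
cylinder (syringe) phantom of known diameter 4.7 mm placed 50 mm off-center.
Each transaxial slice is fitted with amplitude · (disk ⊛ Gaussian) over
four parameters (center x, y, amplitude, FWHM) using Nelder–Mead.  The
disk–Gaussian convolution is radial and evaluated analytically through the
noncentral-χ² CDF, sampled on a 4× oversampled pixel grid and box-averaged
so the model represents voxel-integrated values (point sampling biases
small-FWHM fits).  Initialization uses the argmax of a smoothed copy of the
slice (a whole-slice centroid is noise-fragile), amplitude = max intensity,
FWHM = twice the in-plane voxel size; the fit restarts once from a
perturbed start if the simplex stalls or hits the FWHM bounds
(0.2–40 mm).  Per-slice FWHMs over central slices (free of cylinder-end
effects) are averaged.  The transaxial FWHM is then applied isotropically
in 3-D — a documented approximation, since only the in-plane width is
measured.  The same phantom, replayed with the dynamic frame schedule,
yields the frame-duration bias curve: mask-mean activity per frame
normalized to its time average (mean ≡ 1 by construction).

**GTM extraction.**  Convolving the partial-volume map with the PSF
(unit-sum Gaussian kernel; border mode preserves constants) yields an
arterial weight w per PET voxel that accounts for spill-in and spill-out.
Within the region of all voxels no farther than 2 × FWHM (Euclidean, mm,
via exact distance transform) from the nearest arterial voxel (partial-
volume coefficient ≥ 0.5, configurable), each frame is modeled as
PETᵥ = wᵥ·C_art + uᵥ·C_ext — a massively overdetermined linear system
solved by closed-form 2 × 2 normal equations.  The extraarterial basis is
u = 1 − w by default, i.e. the extraarterial compartment fills all
non-arterial space uniformly; blurring an explicit complement mask instead
is selectable, and the two differ only near the artery by a few percent.
The solve is unconstrained: negative early-frame estimates are legitimate
noise and are flagged, never clipped.  The per-frame C_art curve, indexed
by frame mid-times, is the IDIF.

**Cross-calibration.**  After bolus passage (150–300 s) arterial tracer
concentration is spatially homogeneous, so the IDIF frames and the blood
samples — drawn at a distant site with different delay and dispersion — can
be compared free of bolus dynamics.  Per subject, cc = mean(AIF)/mean(IDIF),
with a *linearly* propagated error σ(cc) = σ(AIF)/mean(IDIF) +
σ(IDIF)·mean(AIF)/mean(IDIF)²; the standard deviations are computed after
removing any linear trend inside the window (both series are detrended;
only the fluctuation estimate, not the means).  The group factor is the
reliability-weighted mean with weights wᵢ = 1/σ(ccᵢ) and standard error
n/Σ(1/σ(ccᵢ)), algebraically equal to Σwᵢσᵢ/Σwᵢ.  Noise-free subjects
(σ = 0) receive a capped weight of 1e12 to keep the average finite.  IDIF
in-window points are frames whose mid-time falls in the window; blood
samples enter by sample time; no interpolation is applied.  The whole-scan
area under the curve uses the trapezoidal rule with a virtual (0, 0) point
prepended when integrating from injection time.

## Synthetic phantoms

The generator emulates the three acquisitions of a sheep neck examination
with full ground truth; all tests run on it, no scanner data is required.

* **TOF-MRA**: 96 × 96 × 64 voxels at 0.5 × 0.5 × 0.7 mm.  Two artery
  tubes of radius 3 mm run axially at diagonal in-plane offsets
  (±9.5, ±9.5) mm — about 27 mm apart, so the 2 × FWHM GTM region around
  one artery never reaches the other — with a small quadratic in-plane bow.
  Vessels are intensity 1.0, the neck disk 0.08, air 0; a random quadratic
  multiplicative bias field (±20%, emulating coil inhomogeneity) and
  additive Gaussian noise (σ = 0.02) degrade the image after the truth
  masks are recorded.
* **Dynamic PET**: 64 × 64 × 32 voxels at 1.40 × 1.40 × 2.03 mm, 46 frames
  (20 × 3, 12 × 5, 12 × 10, 2 × 30 s).  The arteries carry a gamma-variate
  input function (peak 40 kBq/mL at ~25 s, 25% recirculation plateau); the
  rest of the field of view holds a one-tissue-compartment response
  (K₁ = 0.4 mL/min/mL, k₂ = 0.9/min set the shape; the amplitude is scaled
  so the steady-state intra/extraarterial ratio equals the configured
  target, 3.0 by default, exactly).  A catheter tube (radius 1.5 mm,
  40 kBq/mL residual) beyond the second artery pulls the PET center of
  gravity to that side.  The scene is displaced by a quadratic motion
  polynomial (default ≈1–3 mm; tests inject up to 9 mm), rasterized on a 2×
  oversampled grid, blurred with the 6.86 mm Gaussian PSF, box-averaged to
  PET voxels, frame-averaged, and degraded with Gaussian noise of variance
  ∝ mean/duration — reproducing the short-frame variance behavior of
  counting statistics without simulating reconstruction.
* **Blood samples**: the true input function delayed by 10 s, dispersed
  with an 8 s exponential kernel, sampled every 3 s to 120 s and at
  150/180/210/240/300 s, with 3% multiplicative noise.

Deliberate simplifications: tissue fills the whole PET field of view (no
air/tissue boundary), making the uniform-background GTM assumption exact;
arteries span only the MRA slab so mask and scene stay consistent at the
axial ends; there is no attenuation, scatter, decay, or reconstruction
model, no rete mirabile, and no axial motion.  Passing tests therefore
demonstrate the correctness and noise behavior of the algorithm under its
own model assumptions — not robustness to reconstruction artifacts,
non-uniform background uptake, or through-plane motion in real data.

## Numerical choices and degenerate inputs

* Masses ≤ 0 inside a filter sphere (air) yield p = 0 silently; a point
  mass is likewise degenerate.
* Histograms with no interior local minimum (constant or monotone data)
  raise an error asking for a manual threshold rather than guessing.
* Fewer than three valid alignment slices fall back to a mean (degree-0)
  shift with a warning; a missing PET slice invalidates only that slice.
* Gaussian kernels are truncated at 6σ so unit mass holds to <1e-8.
* The GTM normal equations refuse to solve when the arterial weights have
  no spread (variance ≤ 1e-12) — an all-background region is singular.
* All randomness flows through explicit integer seeds; identical
  (config, seed) pairs reproduce every artifact bit for bit.

## Problem sizes

Default test problem sizes: full-resolution single subjects for the stage
tests, a 10-subject cohort for the group cross-calibration, 16 syringe
slices per PSF estimate (4 per noisy replicate), and a reduced 48 × 48 × 32
phantom for command-line plumbing tests.  These sizes were chosen so the
complete suite exercises every stage at the study's native voxel grids
while staying small enough to iterate on quickly.

## Known limitations

* The PSF is a single isotropic Gaussian; spatially varying or
  non-Gaussian responses are out of scope.
* The two-region GTM assumes one artery plus a uniform background;
  additional compartments (e.g. nearby hot structures) bias C_ext first.
* Alignment is translational and in-plane only; rotations and axial motion
  are not corrected.
* The frame-bias curve is reported, not applied as a correction.
* Blood delay/dispersion are not corrected; comparisons are restricted to
  the steady-state window where they cancel.
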