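# Methods

`petrad` implements a PET radiomic measurement chain — tumor
delineation, intensity discretization, feature extraction and
cross-condition comparison — together with a synthetic paired-scanner
phantom generator, so that the stability of radiomic features across
scanners and scan protocols can be studied end to end without patient
data. This note records the models, the parameters that matter, and
the design choices made where conventions genuinely diverge.

## Segmentation: contrast-oriented adaptive threshold

The tumor volume of interest (VOI) is the 26-connected set of voxels,
containing the hottest voxel of an operator-style search box, whose
uptake strictly exceeds

    T = β · I70 + Ibgd,      β = 0.3

where I70 is the mean uptake over the connected contour of voxels above
70 % of the search-region maximum, and Ibgd is the mean uptake in a
background shell 2 voxels thick located 6 voxels outside that contour,
restricted to voxels below 2.5 SUV. β = 0.3 is taken as a calibrated
constant (it was originally optimized against phantom measurements with
known sphere volumes); re-deriving it is out of scope.

Conventions that the verbal definition leaves open, fixed here:

* **Shell distance** is counted in binary-dilation steps with a full
  3×3×3 structuring element, i.e. Chebyshev voxel distance. The shell
  is the set at distance in (6, 8] steps from the core. Both the gap
  and the thickness are configurable.
* **Strict `>`** is used at both thresholds (the 70 % contour and T);
  voxels tied exactly at the threshold are excluded.
* The **2.5-SUV cap applies only to shell voxels**, never to the VOI.
* The **search region is required input**. In the synthetic study it is
  the ground-truth tumor bounding box padded by 16 mm, standing in for
  the operator's visual tumor selection; it exists to stop a hot spot
  elsewhere in the field of view from capturing the component search.
* A search region with zero contrast (constant uptake) raises a
  degenerate-input error rather than returning an arbitrary region.

## Discretization: absolute resampling with fixed bounds

VOI intensities are mapped to integer gray levels by
`R = round[bins · (I − lower)/(upper − lower)]` with fixed bounds
(default 0 and 25 SUV) shared across all lesions, giving absolute bin
widths of 3.125, 0.390625 and 0.09765625 SUV at 8, 64 and 256 bins
(3.1 / 0.4 / 0.1 at the reported precision). Fixed bounds decouple the
gray-level scale from each lesion's own range; per-lesion min–max
rescaling is deliberately not offered because it couples texture values
to tumor volume.

Numerical choices: rounding is half-away-from-zero (banker's rounding
would flip isolated levels); the raw formula's level 0 (intensities
within half a bin of the lower bound) is merged into level 1 so levels
index 1-based matrices — for tumor VOIs, whose uptake is far above the
lower bound, this branch is essentially unreachable; intensities
outside the bounds are clipped and the clipped-voxel count reported,
since the 25-SUV ceiling is a cohort-specific convention, not a law.

## Features

Eight features per (VOI, bin configuration):

* **SUVmean, TMR** on raw (undiscretized) SUV; TMR divides the VOI mean
  by a reference muscle-region mean.
* **Skewness m₃/m₂^{3/2}** and **non-excess kurtosis m₄/m₂²** of the
  discretized level distribution, with population (divisor-N) moments.
  Non-excess kurtosis (Gaussian → 3) was chosen because reported values
  for real tumors sit near 2–3, not near 0. A config switch computes
  the moments on raw SUV instead.
* **GLCM entropy −Σ p log p and homogeneity Σ p/(1+|i−j|)** from the
  3-D co-occurrence matrix over the 13 unique voxel offsets at
  Chebyshev distance 1, symmetrized (each pair counted in both orders)
  and normalized per direction.
* **GLRLM SRE (1/N_r)Σ r(i,j)/j² and LRE (1/N_r)Σ r(i,j)j²** from
  maximal same-level runs of consecutive in-mask voxels per direction;
  any out-of-mask voxel breaks a run.

Open conventions, each a documented switch rather than a silent guess:
each textural index is computed **per direction and averaged** over
directions with at least one pair/run (pooling all directions into one
matrix first is the alternative, `aggregation="pooled"`); the entropy
**log base defaults to 2** (bits) and may be set to 10 or e; texture
neighborhoods are **1 voxel regardless of mm anisotropy** (the
conventional definition; no mm-based offset weighting).

A VOI with a single gray level is legal for texture (entropy 0,
homogeneity 1) but leaves the histogram shape undefined: skewness and
kurtosis are reported as NaN with a `degenerate_histogram` flag so
cohort extraction continues.

## The phantom generator

The generator emulates the *statistical structure* of a paired
three-condition study of the same tumor, not PET physics: no sinograms,
reconstruction, scatter or randoms, and the attenuation-correction
error is a scalar multiplier, not an anatomy-dependent map. Each
subject is a spherical tumor (default radius 15 mm) with a smooth
multiplicative texture — seeded white noise Gaussian-smoothed to a
6-mm correlation length and scaled so the tumor voxel SD equals the
requested heterogeneity amplitude — in a uniform background with a
separate muscle box. Defaults: tumor mean 9.1 SUV, heterogeneity
1.8 SUV, background 1.0 SUV, muscle 0.7 SUV; these put TMR near 13 and
give nondegenerate texture at 64 bins.

Each condition applies, in a fixed order (so outputs are reproducible):
tumor-uptake scaling → attenuation bias → additive Gaussian noise →
clipping of negatives to zero (counted) → 4-mm FWHM Gaussian
post-smoothing → trilinear resampling onto the condition grid. The
three default conditions are:

| condition     | grid (mm)    | uptake scale | AC bias | noise sd (SUV) |
|---------------|--------------|--------------|---------|----------------|
| early         | 4 × 4 × 2    | 1.0          | 1.0     | 0.3            |
| delayed-short | 4 × 4 × 2.78 | 1.3          | 0.9     | 0.5            |
| delayed-long  | 4 × 4 × 2.78 | 1.3          | 0.9     | 0.5/√5 ≈ 0.224 |

The delayed uptake scale of 1.3 reflects the typical FDG increase of a
tumor between an early and a ~1-h-later delayed scan; the MR-based
attenuation bias of 0.9 is a plausible magnitude for soft-tissue-only
attenuation maps near bone (no authoritative per-site value exists, so
it is an explicit free parameter); noise scales as 1/√(acquisition
duration), the standard count-statistics surrogate, making the 2-min
and 10-min reconstructions differ by √5.

Cohorts draw per-subject lognormal random effects on radius, uptake
contrast and heterogeneity (log-SDs 0.12 / 0.30 / 0.25), shared across
that subject's conditions — this is what induces the cross-condition
correlation the paired design assumes. The texture realization is also
a subject-level effect: with all variability switched off, subjects are
exact replicates. Seeds derive from the master seed through
`SeedSequence(master, spawn_key=(subject, condition, stage))`, so
adding a subject or condition never perturbs existing data.

What passing tests on these phantoms do **not** show about real data:
real tumors are not spheres with Gaussian-correlated texture, PET noise
is neither Gaussian nor spatially white after reconstruction, and the
MR-attenuation error is spatially structured near bone. The phantoms
establish that the measurement chain is correct and that its comparison
statistics behave as designed under a known data-generating process —
not that any particular feature is stable in patients.

## Comparison statistics

Condition effects are tested per (feature, bin count) with the one-way
repeated-measures ANOVA sum-of-squares decomposition
(SS_total = SS_subjects + SS_conditions + SS_error;
F = MS_cond / MS_err on (k−1, (n−1)(k−1)) df). The implementation is
the direct decomposition, cross-checked in the tests against an
independent textbook oracle and against `pingouin.rm_anova`. Sphericity
is assumed (no Greenhouse–Geisser correction) and flagged in the
output. Degenerate inputs: a zero condition effect returns F = 0,
p = 1 even when the error term is also zero (identical conditions are
simply "no evidence of difference"); a zero error term with a nonzero
effect raises, since F is then unbounded.

Post-hoc pairwise comparisons are paired two-sided t-tests with
Bonferroni adjustment across the three pairs by default (`holm` and
`none` are available); the adjustment choice is stated because reported
pairwise p-values in this literature often leave it implicit. Percent
differences are stored signed at full precision and rounded to integer
percent only at the reporting layer. Pearson r uses the standard
product-moment form with the t-transform p-value and refuses constant
series.

## Problem sizes

The default synthetic study is 8 subjects × 3 conditions × 3 bin
configurations on 40×40×40 grids (~160×160×80 mm), which runs the full
pipeline in a few seconds and gives VOIs of a few hundred voxels —
comparable to a small primary-tumor cohort. The statistical calibration
check uses 5,000 simulated null tables at n = 8, k = 3; the texture
oracle comparison uses 120 random VOIs up to 5×5×5 at 8/64/256 bins.

## Known limitations

* The AC bias is scalar; site-dependent spatial structure (bone
  proximity) is out of scope.
* No DICOM input and no inter-scanner registration: each image is
  analyzed on its native grid, VOIs delineated independently per
  condition.
* The texture feature set is deliberately minimal (the 8 features
  above); the wider IBSI families (GLSZM, NGTDM, shape) are out of
  scope.
* Entropy magnitudes depend on the log base and the aggregation
  convention; comparisons across software require fixing both switches.
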