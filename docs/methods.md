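# Methods

## The problem

Regional lung function can be imaged with ventilation/perfusion (V/Q)
PET/CT: inhaled ⁶⁸Ga-labelled carbon nanoparticles map ventilation,
intravenous ⁶⁸Ga-macroaggregated albumin maps perfusion.  The clinically
useful quantity is the *functional volume* — the part of the anatomical
lung that is ventilated (or perfused) — expressed as a percentage of the
whole-lung (WL) volume delineated on CT.  Manual contouring of these
volumes is accurate but slow and operator-dependent; the automatic
alternative is a threshold at a fixed percentage of the maximum PET
value inside the lungs ("%max").  This package implements that method
end to end, together with the evaluation machinery (volume differences,
Dice, Pearson, Bland-Altman, correlation with pulmonary-function tests)
and a digital phantom cohort with known ground truth on which the whole
chain can be validated quantitatively.

## The delineation model

1. **Whole lung.**  Voxels with HU below a cutoff (default −400, between
   aerated lung ≈ −950..−500 and soft tissue ≈ 0..100) form the
   candidate mask.  Outside-body air is removed as border-connected
   components; components smaller than 100 ml are dropped; the up-to-two
   largest components are kept (left and right lungs may merge at the
   mediastinum, hence "up to two" rather than "exactly two");
   morphological closing (6 mm) and hole filling smooth the contour;
   trachea/main bronchi are optionally removed by a region grow seeded
   on the top slice at HU < −950.  Closing and filling only ever add
   voxels, so cleanup is monotone relative to the raw threshold mask.

2. **Reference maximum.**  The %max method stands or falls with the
   maximum.  On ventilation scans, focal airway deposition ("hot
   spots") produces maxima several-fold above parenchymal activity;
   thresholds derived from a contaminated maximum shrink every
   functional volume.  The `auto` policy flags 26-connected clusters of
   voxels above 1.5× the in-lung 99.5th percentile whose volume is at
   most 5 ml, dilates the flags by 8 mm (one PSF FWHM) so the blur skirt
   of a focus cannot replace it as the maximum, and takes the maximum
   over the remaining lung.  The 5 ml cap reflects that a ~1 ml
   deposition observed through an 8 mm PSF spans 3–5 ml above the flag
   threshold; a tighter cap would never fire on realistic foci.  Two
   manual policies (`manual_value`, `manual_roi`) expose the operator
   procedure directly.  If no cluster is flagged the estimate equals the
   raw maximum.

3. **Thresholding.**  `mask(c) = {v ∈ WL : A(v) ≥ (c/100)·A_max}`,
   volume reported as `100·|mask|/|WL|`.  The inclusion rule is `≥`
   (a voxel exactly at the threshold is inside), stated for
   reproducibility.  Because all cutoffs share one maximum, sweep masks
   are nested exactly and volumes are non-increasing; because the
   threshold is fractional, masks are invariant to rescaling the PET
   values.  The standard sweep is 5, 10, 15, 20, 25, 30, 40, 50 %max.

4. **Adaptive protocol.**  A fixed threshold is a poor fit for
   individual patients, so the recommended workflow starts at 15%max
   and greedily walks to adjacent candidate cutoffs (default 5–30%max,
   the range observed clinically) while an objective improves.
   `match_reference` minimises |Δvolume| against a reference contour
   (the evaluation setting); `plateau` minimises the local |dV/dc|
   (the flattest response, a reference-free surrogate for visual
   judgement — our construction, not a published operational
   criterion).  The full trajectory is returned for audit.  Greedy
   descent from 15 can never end worse than 15.

## Evaluation statistics

* Signed volume difference, automatic − reference, in %WL points; both
  terms share one WL denominator.
* Dice `2|A∩B|/(|A|+|B|)`; the Dice of two empty masks is defined as
  1.0 (identical masks) with a logged warning — any other convention
  breaks the identity property.
* Bland-Altman: bias = mean difference, SD with the n−1 denominator,
  limits of agreement bias ± 1.96 SD, extremes recorded.
* Pearson r with a two-sided p from the t distribution (n−2 df);
  significance flagged at p < 0.05.  No multiple-testing correction is
  applied across the PFT correlation table; the choice is logged.
* Per-case best cutoff = argmin |volume difference|; ties break toward
  the cutoff nearest 15 (the protocol's starting threshold), then the
  lower one.  Cohort-optimal cutoff = argmin |mean volume difference|.

## The phantom

Each case: two ellipsoidal lungs (−750 HU) inside a soft-tissue body
(40 HU, thin 300 HU shell) surrounded by air (−1000 HU); grid 64×64×48
at 4 mm isotropic (PET-resolution desk scale; one full case runs in
about a second).  PET activity inside the lung is
`base · (1 + g·depth) · m(v)` with base 200 expected counts/voxel,
anterior–posterior gradient g = 0.5 (gravity-dependent supine
physiology), and a defect multiplier m ∈ [0, 1); outside the lung a 2%
scatter floor.  Spherical defects with m < 0.5 realise a target
functional fraction; their common radius scale is solved by bisection
on the rasterised geometry (sub-voxel centre jitter breaks lattice
symmetry so the bisection can land within 1.5% of the target).  Airway
hot spots are additive truncated-Gaussian blobs (σ = r/1.5, support 2σ,
default r = 6 mm ≈ 1 ml) whose peak is `multiplier ×` the *normal*
local activity — deposition happens in airways and does not scale with
parenchymal defects; they go on ventilation images only.  The image
chain is: hot spots → Gaussian PSF (FWHM 8 mm) → Poisson noise.

**Ground truth** is defined on the noiseless, unblurred, gradient-free
activity: a lung voxel is functional iff m ≥ 0.5.  This emulates an
expert's physiological reference contour, is independent of the %max
method under test, and is invariant to the gradient (which rescales
activity of tissue that is functional either way).

**Noise** is drawn by inverse-CDF transform of a seed-determined
uniform field rather than sequential Poisson sampling, so two phantoms
differing only locally (e.g. a hot spot added) share identical noise
away from the difference — the paired-phantom experiments depend on
this common-random-numbers property.  The marginal distribution is
exactly Poisson.

**Cohorts** draw functional fractions uniformly (default 0.4–0.9),
1–3 defects, and a hot spot with probability 0.5.  Each PFT index is
`intercept + slope·fraction + N(0, sd)`, clipped to a physiological
range.  Default couplings give population correlations of ~0.78
(FEV1/FVC), 0.61 (FEV1 %pred), 0.43 (DLCO %pred) and 0.30 (FVC %pred)
with the true fraction — strong for the obstruction ratio, progressively
weaker down the list, the pattern reported for reference-standard
functional volumes in clinical V/Q PET/CT cohorts.
`coupling_for_r` constructs a coupling with any desired population r.

### What the phantom does *not* model

Real anatomy (lobes, fissures, vessels, diaphragm shape), attenuation
and scatter physics, reconstruction artifacts, respiratory motion and
gating, V/Q mismatch (ventilation and perfusion share one truth per
case), inter-observer variability of the manual reference (truth is
noise-free; a morphological-jitter hook is deliberately left out of
scope).  Tests passing on phantoms therefore demonstrate correctness of
the algorithmic chain and its noise/blur robustness — not clinical
accuracy on patients.

## Numerical choices and degenerate inputs

* Lattices must agree within 10⁻³ mm; nothing resamples silently —
  `resample_to` (trilinear for volumes, nearest-neighbour for masks) is
  an explicit step.
* Masks live on the voxel lattice; volume = count × voxel volume.  All
  downstream quantities are ratios, so sub-voxel surfaces buy nothing.
* Non-finite voxels at load are repaired to the volume minimum and
  logged.
* Empty WL, empty candidate lists, all-excluded lungs, non-positive
  maxima, n < 2 cohorts and zero-variance correlations raise with
  specific messages rather than propagating NaNs.
* All computation is at full precision; CSV output is written at six
  decimals, so re-running a deterministic pipeline is byte-identical.

## Problem sizes used in the validation suite

Unit tests run 32³ phantoms (a few ms each).  The end-to-end recovery
experiments use the default 64×64×48 grid: 10 master seeds × 30-case
cohorts for cutoff-stability/MAE, 20 phantoms for sweep structure, and
500 truth-only 30-case replicates at 32³ for correlation-stage
calibration.  These sizes were chosen so the full suite completes in a
few minutes on one CPU while keeping Monte-Carlo margins comfortable.

## Known limitations

* The percentile-based hot-spot flag assumes the lung is much larger
  than any focus; on very small lungs (≲ 5000 voxels) a focus can
  contaminate the 99.5th percentile itself and escape flagging.
* The HU-threshold lung segmentation is not intended for consolidated
  or pathological lungs; `manual_adjust` is the scripted escape hatch.
* Only non-gated, pre-aligned 3-D inputs are supported; CT/PET
  alignment must be handled upstream.
* The cohort-optimal cutoff on phantoms (typically 30%max) is a
  property of the phantom's noise/blur regime — the maximum over many
  noisy voxels sits well above the mean parenchymal activity, so larger
  fractional cutoffs compensate; it is not a clinical recommendation.
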