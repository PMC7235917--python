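# Methods

This note documents the model behind each stage of the pipeline, the
parameters that matter, the conventions that had to be fixed where common
practice varies, and what the phantom-based validation does and does not
show.

## Image model and conventions

All images are 3-D scalar grids with an affine voxel-to-world map: world =
origin + orientation · (index ∘ spacing), world coordinates in LPS
millimetres, 0-based indices, and values located at voxel centres. NIfTI-1
is the canonical on-disk format; DICOM series are converted into the same
model on read. PET inputs are activity concentration (Bq/mL) already
corrected for attenuation, scatter, randoms and dead-time; CT inputs are
Hounsfield units and are sanity-checked against the physically plausible
range [−1024, 4000].

**SUV.** Body-weight SUV with a 1 g/mL tissue density, the dominant clinical
convention. The injected dose is decay-corrected to *scan start* (not
injection time): scanners differ here, and the choice only rescales all SUVs
of a patient by a common factor, so it cancels out of the method's central
ratio (graft uptake vs. muscle-derived threshold) but must be fixed for the
absolute numbers to be comparable. The half-life default is 110 min (¹⁸F).

## VOIs and fusion

VOIs are analytic cylinders (centre, unit axis, radius, height) rasterized
with a centre-inside rule — a voxel belongs to the VOI iff its centre lies
inside the cylinder. This is simple, deterministic, convergent (rasterized
volume → πr²h as spacing → 0; measured: 1.1% error for a 20 cm³ cylinder at
1 mm spacing) and matches typical clinical ROI software. No partial-voxel
weighting. The cylinder axis must be given explicitly in the config; nothing
forces it to be axial.

The right-side muscle VOI is produced by mirroring the left across the
mid-sagittal plane x = x₀ (centre reflected, axis x-component negated,
radius/height unchanged), so both reference regions have identical
dimensions by construction.

Graft VOI placement is an *input*, not an algorithm: the original procedure
relies on observer judgement (surgical report plus the visible uptake
volume), which is not a reproducible rule. VOIs therefore come from the run
config; the package mirrors and rasterizes them but does not place them.
When placing graft VOIs, keep them clear of cortical bone — bone takes up
NaF avidly and any bone voxels inside the VOI survive the threshold and
inflate SUVtotal (measurably so on phantoms).

**Rigid fusion.** Transforms are parameterized as intrinsic z-y-x Euler
angles (degrees) about an explicit centre plus a translation (mm). Metadata
fusion returns the identity when both headers agree; when they differ, the
grids are assumed congruent acquisitions of the same anatomy and the
transform aligns the PET orientation and grid centre onto the CT's. Manual
refinement is a second rigid transform composed on top, supplied in the
config (no GUI). PET is always resampled (trilinear; nearest available)
onto the CT grid — CT is the geometry reference because the HU mask lives
there — with out-of-field fills of −1000 HU (CT) and 0 (PET).

## Muscle reference and threshold

The muscle VOI is restricted to the fixed window **0–250 HU** (inclusive at
both ends), excluding fat (< 0 HU) and bone (> 250 HU). On noise-free
phantoms this recovers exactly the generator's muscle voxels.

**SUVpeak** is the maximum, over sphere centres restricted to voxel centres
inside the mask, of the mean SUV over the voxels whose centres fall in a
1 cm³ sphere intersected with the mask. A placement is valid only if at
least 50% of the sphere's voxels are in the mask (guards against means over
a handful of boundary voxels); ties break to the lowest C-order linear
index. This is exhaustively checked against a brute-force oracle. Masks
smaller than the sphere raise an error rather than returning a degraded
estimate.

The per-patient graft threshold combines the two sides' muscle SUVpeaks.
The combination is configurable (`mean`, `max`, `per-side`) and logged;
`mean` is the default as the least biased symmetric choice. The threshold
comparison is **≥** (inclusive): keeps boundary voxels, deterministic.

## Graft segmentation and metrics

Voxels inside the graft VOI with SUV ≥ threshold are labelled; connected
components are computed with 26-connectivity (conventional for PET hot-spot
work; 6 available by config) and components with volume < 1.0 mL are
removed. The filter is implemented as ≥ 1.0 mL retention (strict > by
config): voxel quantization makes exact equality measure-zero in practice.
An empty post-filter mask is a valid zero-uptake result, not an error.

**SUVtotal = SUVmean × segmented volume (mL)** — the total-lesion-uptake
convention, the only definition under which "SUV·mL" is coherent.

## Partial volume correction

Finite scanner resolution (modelled as an isotropic Gaussian PSF, FWHM a
config scalar, default 6 mm) makes a small hot object's measured mean lower
than its true mean. The correction is a local-background spill-out
correction of the same family as the vendor algorithms used in clinical
software:

- background B: median SUV in a shell around the segmented mask, offset by
  one FWHM (to stay clear of spill-out) and one FWHM thick; other segmented
  regions are excluded from the shell;
- retention r: the mean over the mask of the mask indicator convolved with
  the Gaussian PSF (the fraction of the object's signal that stays inside);
- corrected mean = (observed mean − B·(1 − r)) / r, clipped from below to
  the observed mean (the model describes a hot region on a colder
  background; a "correction" that lowers the mean signals model violation
  and is not applied);
- cSUVtotal = corrected mean × volume.

If r < 0.05 the correction is numerically unstable (near-total spill-out);
the uncorrected value is returned with a warning flag rather than a wild
extrapolation.

The correction is exact when the mask coincides with the true object
boundary, B is the true background, and the object is uniform; its accuracy
degrades with delineation error. For a uniform object on a uniform
background under a Gaussian PSF the boundary sits near the
background-corrected 40%-of-maximum level, so the package provides
`estimate_local_background` + `delineation_threshold` for a two-pass
delineation. On noise-free spheres (6 mm FWHM) this recovers the true mean
within 5% for diameters ≥ 15 mm, and the corrected mean is never farther
from truth than the uncorrected one anywhere in the 10–40 mm sweep. With the
*fixed muscle-peak threshold* the graft mask includes a background halo
(muscle SUVpeak sits well below the graft/background 50% level), so
cSUVtotal corrects an over-segmented region and runs above the naive truth
product; SUVtotal itself is much less sensitive because over-segmentation
trades mean against volume.

The vendor algorithms' exact formulations are unpublished; equivalence with
them cannot be asserted, only recovery performance on phantoms.

## Digital phantom

The phantom emulates the posterior lumbar anatomy the method operates on: an
elliptical soft-tissue body (40 HU, SUV 0.5) with a subcutaneous fat slab
(−100 HU, SUV 0.3), bilateral erector-spinae-like muscle cylinders of
~20 cm³ (50 HU, true SUV 1.0) above the graft level, a central cortical-bone
block (700 HU, SUV 3.0), and bilateral ~4 cm³ graft cylinders adjacent to
the bone (true SUV 5.0 by default — an active graft about 5× muscle).
Regions are painted in declaration order (first wins on overlap); truth
masks and per-region volumes are returned exactly.

The PET side is the piecewise-constant truth convolved with the Gaussian
PSF (default 6 mm FWHM, typical of the whole-body scanners this protocol
runs on), plus Gaussian noise with variance proportional to the local mean —
a pseudo-Poisson surrogate acting on the blurred image. Default noise scale
0.01 ("mild": σ ≈ 0.1 SUV at SUV 1), seeded and reproducible. An optional
rigid misalignment perturbs the PET header geometry so metadata fusion can
be validated against the known answer. The phantom deliberately does *not*
model sinogram-level physics (attenuation, scatter, randoms, reconstruction
artefacts), anatomical texture, respiratory motion, or scanner-specific
PSFs: passing phantom tests shows the *algorithmic* chain is correct and
self-consistent, not that clinical accuracy on real scanners is guaranteed.
Default grid: 96×96×64 at 2 mm isotropic (the method's resolutions of
interest at tractable cost; the CT slice thickness of clinical protocols is
coarser, which only makes the HU mask easier).

Synthetic cohorts draw n = 18 patients with fusion probability 4/18 by
default (the prevalence regime this kind of study faces), clinical scores as
independent uniforms within observed ranges truncated to instrument bounds
(VAS 0–10, ODI 0–100, TAN 0–30, EQ-5D 0–1, walking distance 0–1000 m), and
summed uptake as a truncated normal (mean 1224, SD 330 SUV·mL) with a
configurable fused-vs-unfused shift (default −46 SUV·mL; 0 gives the null).
No correlation structure between scores is imposed — none is established.

## Statistics

- Descriptives: median [min, max] per fusion group; even-n medians are the
  mean of the central pair.
- Univariate logistic regression of fusion on one predictor at a time,
  maximum likelihood; OR = exp(β) with **Wald** 95% CI and p (the
  reproducible-from-coefficients choice). Perfect separation is detected
  (non-overlapping class ranges, or diverging standard errors) and flagged
  instead of reporting a spurious finite OR. ORs are per unit of the
  predictor's own scale; the report prints values unscaled, so a 0–1 index
  (EQ-5D) naturally produces extreme-looking ORs with wide CIs.
- Spearman rank correlation (average ranks for ties, two-sided p) between
  each uptake metric and each 12-month-minus-baseline score change.
- Missing data: available-case per test, no imputation. No multiplicity
  correction — the analysis is explorative and small-n; the report states
  the number of tests run.

Null calibration: on cohorts generated with zero uptake effect, the
logistic 95% CI for the uptake OR covers 1 in ≥ 90% of seeded replicates
(measured 92–99% across seeds at 100 replicates of n = 100).

## Numerical choices and degenerate inputs

- SUVpeak ties: lowest linear index; sphere membership uses voxel-centre
  distance ≤ r with a 1e-9 slack against float jitter.
- Cylinder membership uses a 1e-12 slack on the squared radial distance.
- Empty HU-windowed masks and empty segmentations warn and return empty
  results; SUVpeak on a mask smaller than the sphere raises.
- Gaussian blur at the phantom boundary uses zero-padding; activity is
  conserved (< 0.5% loss) whenever the body is inside the field by a few
  FWHM. The default body extends through the z-faces (a torso section), so
  global activity bookkeeping should use a compact body.
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  config + seed gives byte-identical outputs.

## Known limitations

- The fixed muscle-peak threshold quantifies what the VOIs cover; a graft
  edge outside the VOI, or below the threshold, is not recovered — no
  edge-completion step is attempted.
- cSUVtotal inherits delineation bias (see above); it is comparable across
  patients processed identically, not an absolute activity measurement.
- The phantom validation bounds algorithmic error only; scanner-specific
  effects are out of scope.
- Metadata fusion assumes either a shared frame of reference or congruent
  acquisition extents; wildly different fields of view need a manual
  adjustment in the config.
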