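# Methods

This note records the model, the conventions chosen where the clinical
literature leaves them unstated, and what the synthetic experiments do and
do not demonstrate.

## The partial uninvolved construction

All geometry lives in the DICOM patient coordinate system (mm; +x left,
+y posterior, +z superior).  Given a PTV mask and an OAR mask on a shared
voxel lattice, the partial uninvolved OAR is

```
partial(OAR) = { v ∈ OAR : z(v) ∈ [z_min(PTV) − m, z_max(PTV) + m] } \ PTV
```

with margin `m = 10 mm` by default.  Three interpretation decisions are
deliberate and exposed:

* **The margin is a z-band crop only.**  "Within m of the PTV edge
  superiorly and inferiorly" is applied to the axial slice coordinate, not
  as a 3D Euclidean distance: the OAR's in-plane extent is untouched on
  retained slices, including the slices spanning the PTV itself.
* **Overlap removal is plain boolean subtraction** of the PTV mask, with no
  additional margin.
* **The band boundary is inclusive** ("within" reads as ≤): a voxel center
  exactly m from the PTV edge is retained.  Band membership is tested on
  voxel-center z against the continuous interval with a 1e-9 mm tie guard.

Because the band test and the subtraction act on disjoint coordinates
(z-slab selection vs per-voxel membership), their order is immaterial; the
implementation applies both in one vectorized pass and is verified against
an independent per-voxel filter.

## Voxelization

Occupancy is decided at voxel centers: a voxel belongs to a structure iff
its center lies inside the contour polygon set of the nearest contour slice
(nearest-slice assignment limited to half the contour slice spacing).
Multiple rings on one slice combine by the even-odd rule, the standard
clinical-system convention, so donut/hole topologies work.  There is no
partial-volume weighting — determinism and oracle-checkability were judged
more valuable than sub-voxel accuracy, and the rasterized volume of an
analytic shape converges to its analytic volume with error bounded by
surface area × spacing (asserted in the tests).

When no dose grid dictates the lattice, structures are voxelized on an
isotropic 2.5 mm bounding grid (typical pelvic CT slice spacing;
configurable).  When dose operations are involved, the RTDOSE lattice is
used.  Masks resample nearest-neighbor (categorical labels); dose resamples
by trilinear interpolation (continuous field).

Masks are converted back to planar contours (for RTSTRUCT export of partial
structures) by marching squares at the 0.5 level of the padded occupancy
plane.  The 0.5-level line passes midway between occupied and unoccupied
voxel centers, so re-rasterizing the exported contours on the same grid
recovers the original mask exactly; this round trip is asserted in the
tests.

## Agreement scoring

DSC is the usual symmetric `2|A∩B|/(|A|+|B|)`.  The overlay index has no
single standard formula; here

```
OI = |ref ∩ test| / |ref|
```

with `ref` the manual/reference structure — the common convention in
contour-evaluation work.  The reference role is an explicit argument, never
inferred from call order, and OI's asymmetry is intentional.  In partial
mode, both variants are first reduced against the *same* reference PTV,
then scored.  Two empty masks yield an undefined score, reported as
missing — silently scoring empty-vs-empty as 1 (or 0) would bias cohort
means exactly in the regime partial contours create (organs removed
entirely by the band crop).

## Dosimetry conventions

* DVHs are cumulative, binned at 0.1 Gy (0.14% of a 70 Gy prescription),
  with bin-edge ties counting as "receiving" the dose; the curve starts at
  exactly 100% and reaches 0 above the maximum dose.
* Dmax is the plain maximum voxel-sample dose (no D0.035cc surrogate).
* D_p (the dose covering p% of the volume) is the linear-interpolated
  (100−p)th percentile of the dose samples; prescription normalization
  scales the plan by `rx / D98(PTV)` and is idempotent and
  scale-equivariant to floating-point precision.
* Dose metrics are always evaluated on **full** organ masks, even when a
  plan was optimized with partial structures — the fairness rule of the
  comparison framework.

## Statistics

Plan variants are generated on identical per-patient anatomy, so the
default test is the **paired** two-sided Student's t-test on per-subject
differences (an unpaired option exists).  Significance is p ≤ 0.05 with no
multiple-testing correction, matching per-metric clinical reporting; this
is a documented limitation, not an oversight.  All-zero differences give a
degenerate result (p = 1, flagged) rather than an exception; a constant
non-zero difference is flagged and reported maximally significant.

Parity ratios between plans are computed as the **ratio of cohort means**
(`mean(b)/mean(a)`, `a` the "former" plan), pairing one ratio with one
cohort p-value; a mean-of-ratios estimator is available as an option.  The
type-I error of the paired test is Monte-Carlo calibrated in the acceptance
suite (10,000 null replicates, n = 12 pairs).

## The synthetic phantom

The phantom emulates a male pelvis at planning-CT fidelity:

| structure | model | default |
|---|---|---|
| PTV | ellipsoid at origin | semi-axes (30, 28, 25) mm |
| Bladder | ellipsoid, superior-anterior | semi-axes (35, 32, 30) mm, 25 mm anterior offset, 15 mm overlap depth into the PTV's superior surface |
| Rectum | straight z-tube, posterior | radius 12 mm, z ∈ [−60, 40] mm |
| Femoral heads | lateral spheres | radius 22 mm at x = ±68 mm |
| grid | isotropic lattice | 2.5 mm, 96×96×72 voxels |

The **rectum–PTV gap** is the single knob emulating an injectable rectal
spacer, whose role in the analysis is purely geometric displacement:
spacer cohorts default to +10 mm, non-spacer cohorts to −5 mm (overlap,
since a margin-expanded PTV typically overlaps the anterior rectal wall).

**Dose** is analytic, not a treatment-planning surrogate: the prescription
(70 Gy, the 70 Gy/28-fraction regimen this toolkit targets) inside the
analytic PTV with exponential falloff (length 8 mm) with Euclidean distance
outside.  Inside the target the dose carries a mild smooth 3D heterogeneity
(±2% superior-inferior gradient plus low-amplitude incommensurate in-plane
ripples).  The heterogeneity serves two purposes: delivered plans are a few
percent hot/cold rather than flat, and a continuous in-target distribution
keeps coverage percentiles such as D98 well defined instead of collapsing
onto tied per-slice values.  An analytic field gives closed-form and
counting oracles for every DVH quantity, which a realistic optimizer output
never could.

**Cohorts** jitter the template anatomy with per-parameter normal draws
(defaults: semi-axes 2–3 mm SD, rectum radius 1 mm, gap 1.5 mm, overlap
depth 2 mm), truncated at ±2 SD so anatomy stays within the scan field of
view.  Case *i* of a cohort depends only on `(seed, i)`; everything is a
pure function of (spec, seed), and DICOM export is byte-deterministic
(content-hashed UIDs, no timestamps).

**Contour variants** emulating observer/AI variability perturb masks by
isotropic dilation/erosion (Euclidean distance on the lattice), a rigid
z-shift, or boundary noise: voxels in the one-voxel surface shell flip with
probability `min(1, magnitude / (2·⟨spacing⟩))`.  The default 2 mm
magnitude reflects typical inter-observer boundary disagreement for pelvic
organs.  Perturbations can be confined to the PTV-overlap region or to the
region outside the partial-contour z-band; such confined perturbations are
provably erased by the partial construction, which is the mechanism that
makes partial-mode agreement scores higher.  With unrestricted boundary
noise the synthetic cohorts reproduce that direction (partial mean DSC/OI ≥
full): strongly for the rectum, whose PTV interface carries much of its
noise, and by a small margin for the bladder, where the gain from erasing
interface noise is partly offset by the band crop retaining a
high-surface-to-volume inferior cap — at some random draws the bladder
means come out as near ties.

### What the phantom does not show

The phantom has no CT texture, no deformable anatomy, no learned
segmentation model, and its dose is not the output of any optimizer —
plan-quality differences *caused* by planning with partial structures
(knowledge-based model training, VMAT optimization) are outside this
package's scope.  Passing tests demonstrate the correctness of the
geometric construction, the metrics, and the statistics, and the
qualitative behavior of partial-mode scoring under boundary variability;
they do not certify results on patient data, where organ shapes, dose
gradients, and observer behavior are all richer.

## Numerical choices

* Coordinate comparisons (band membership, grid bounds) use a 1e-9 mm
  guard; DVH bin-edge ties use a 1e-9 Gy guard.
* RTSTRUCT vertices are serialized at 4 decimal places (≤ 5 × 10⁻⁵ mm
  round-trip error, against a 10⁻³ mm budget); RTDOSE uses 32-bit scaled
  integers (quantum `max_dose / (2³² − 1)`).
* Contour slices with fewer than 3 vertices or zero area are skipped with a
  warning at rasterization (and on write), rather than rejected at
  construction, so imperfect third-party structure sets remain loadable.
* Degenerate statistics (empty structures, zero denominators, both-empty
  agreement) surface as typed errors or flagged rows, never as silent 0/1.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data:
full-size cohorts of n = 30 cases per arm for the agreement and dosimetry
experiments, 100 jittered reduced-extent (40³-voxel) cases for the
exhaustive partial-construction oracle, and 10,000 replicates for t-test
calibration — sizes chosen so the complete suite executes in well under a
minute per component on a single CPU while keeping Monte-Carlo standard
errors small against the asserted tolerances.
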