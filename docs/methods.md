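# Methods

## Pipeline model

The package treats automated lumbar-disk reading as four stages over a
pair of T2-weighted DICOM series (one sagittal stack, one axial stack):

1. **Vertebral-body localization.**  On the midsagittal image a detector
   produces scored candidate boxes; after IoU-based non-maximum
   suppression (threshold 0.5) the six best boxes are labeled L1…S1 by
   decreasing patient-space z of their centres, and each box centre
   (mean of min/max row and column) is mapped to patient coordinates.
   Fewer than six surviving candidates is a hard error — every later
   stage needs all six midpoints.
2. **Slice-to-level assignment.**  For each axial slice the six signed
   point-to-plane distances `d_i = n·(m_i − S)` are computed.  If exactly
   one adjacent pair `(d_i, d_{i+1})` has strictly opposite signs, the
   slice plane separates those two midpoints and is assigned to the disk
   between them.  Otherwise (slice beyond L1 or S1, or exactly through a
   midpoint — zero is deliberately treated as *no* strict sign to avoid
   double-sign-change ambiguity at measure-zero configurations) the
   assignment falls back to the level whose midpoint-pair gap centre is
   nearest the plane, ties to the more superior level, with a warning.
   A second warning fires when the chosen gap centre is further than a
   plausibility threshold (default 30 mm) from the plane.
3. **ROI localization and cropping.**  A detector returns the single
   highest-scoring disk box (error if nothing clears the score threshold,
   default 0.5); the box is enlarged by a margin fraction per side
   (default 0.25) and clipped, because surrounding structures such as the
   compressed spinal canal carry diagnostic signal.
4. **Classification and fusion.**  Each cropped ROI receives a 3-class
   probability vector; a disk's slices are fused by arithmetic mean of
   their probability vectors followed by argmax.  The mean is the
   simplest permutation-invariant fusion and keeps per-slice evidence
   inspectable in the report.

Coordinates are DICOM LPS throughout; pixel indices are 0-based
(row, column); boxes are half-open.  The first ImageOrientationPatient
triplet is the direction of increasing column index, the second of
increasing row index, and PixelSpacing is (between-rows, between-columns)
— the standard's definitions, asserted once in `io` and relied on
everywhere.

## Backends as contracts

The detectors and the classifier used at clinical scale are deep
networks whose value lies in trained weights; here they are modeled as
contracts (`DetectorContract`, `ClassifierContract`).  The shipped
reference detector is Otsu's global threshold → connected components →
area/solidity filters → tight boxes scored by normalized mean intensity.
The reference classifier extracts eight morphological features from the
thresholded disk mask (posterior-margin prominence, posterior-quarter
lobe narrowness, row-distribution skewness, eccentricity, solidity,
area-normalized posterior protrusion depth, boundary-curvature extremum,
moment-based axis ratio) after aspect-preserving resize to a 128-pixel
square, and fits a multinomial logistic model with the class weights
applied as observation weights.

One numerical choice matters: features are standardized by the pooled
*within-class* standard deviation, not the global one.  Herniated disks
span a wide eccentricity range; global scaling would let that spread
dominate the eccentricity axis and wash out the fine eccentricity
separation between normal and bulging disks, which costs isolated
cross-validation errors.  Within-class scaling preserves that
discriminative direction while keeping the model linear.

## Cost-sensitive loss and evaluation

Class imbalance is handled by inverse-frequency weights
`w_k = N/(K·n_k)` (balanced data ⇒ all weights 1) applied both inside
the weighted cross-entropy `−w_y log p_y` (probability floored at 1e-12)
and as observation weights in the reference model fit.  Evaluation uses
fourfold cross-validation **grouped by subject** and stratified by class
where feasible: per-image splitting would leak a subject's highly
correlated slices across folds and inflate accuracy.  Confusion matrices
are summed over folds; accuracy is the trace over the total, and
per-class sensitivity/specificity come from one-vs-rest collapse, with
undefined rates reported as NaN rather than 0.

## The phantom generator

The generator emulates the *structure* the pipeline assumes, not MR
physics.  A subject is a stack of six vertebral bodies (height 28 mm,
disks 10 mm, so a 38 mm pitch) whose centres are displaced anteriorly by
a half-sine lordosis bow; the bow amplitude is drawn uniformly from
[0, `curvature_amplitude`] mm per subject (default range up to 15 mm,
up to 25 mm in the acceptance cohort) and each disk draws an axial tilt
uniformly from ±`axial_tilt_degrees` (default ±12°).  Eleven sagittal
slices (5 mm apart, 256² pixels at 1 mm) show the bodies as bright
rectangles with dimmer disks between them; three axial slices per disk
are placed strictly between adjacent vertebral midpoints — never beyond
L1 or S1, matching the acquisition the pipeline targets (slices beyond
the lumbar span are available behind `include_flanking_slices` for
fallback testing).  Gaussian noise (sd 0.02 of the foreground level) is
added everywhere; all DICOM tags are derived from the same 3-D model, so
geometry round-trips exactly.

Axial disk cross-sections are parametric shapes chosen for controllable
class separability rather than anatomical realism: a normal disk is a
plain ellipse (semi-axes 22 × 14 mm); a bulge adds a broad
posterior-directed Gaussian radial expansion (relative amplitude
0.40–0.55, angular width 0.7–0.9 rad); a herniation adds a narrow focal
posterior lobe (amplitude 0.80–1.00, width 0.20–0.30 rad).  Disk size
varies mainly through a common ±10% factor with only ±1% independent
per-axis jitter, so the antero-posterior aspect remains a reliable class
cue while absolute size does not.  These ranges make the three classes
geometrically separable by construction — which is exactly what the
classifier-harness checks presuppose; consequently, a perfect
cross-validated accuracy on phantoms demonstrates that the harness,
grouping, weighting and fusion are correct, and says nothing about
accuracy on clinical images, where class boundaries are genuinely
ambiguous.  Class labels per disk are either fixed or sampled from
per-level priors; the default priors follow the class frequencies of a
500-patient clinical cohort (normal/bulge/herniation 1885/1096/574
overall), under which herniation receives an inverse-frequency weight
1885/574 ≈ 3.28 times that of the normal class.

## Problem sizes and determinism

All randomness flows from explicit seeds through `numpy` generators
(cohorts spawn per-subject child seeds via `SeedSequence`), so subjects
are bit-reproducible and two pipeline runs with the same configuration
serialize byte-identically.  The shipped validation suite uses
desk-scale sizes chosen to exercise the statistics without heavy
compute: 50 subjects (750 axial slices) for the assignment study, 20
noise-free subjects for detection quality, 120 ROIs per level for the
classifier harness and 500 for the shuffled-label chance check, 10,000
random frames for geometry round-trips and 1,000 cases against the
brute-force plane-distance oracle.

## Known limitations

* No MR physics: no bias field, partial-volume, or k-space artifacts;
  intensity is a three-level step model plus Gaussian noise.
* Single-frame DICOM only; no enhanced multi-frame MR objects, no
  vendor private tags, no sequence inference.
* No transitional-anatomy handling (lumbarization/sacralization); the
  model assumes exactly six bodies L1–S1.
* The reference backends are phantom-grade stand-ins; clinical use
  requires trained detector/classifier backends plugged into the same
  contracts.
* The midsagittal slice is chosen by the centroid-of-origins rule; on
  clinical data with a laterally offset stack this may differ from a
  radiologist's choice.
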