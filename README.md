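# spinedx

Geometry-driven analysis of lumbar spine MR studies: locate the six
vertebral bodies (L1–S1) on the midsagittal image, assign every axial
slice to its intervertebral-disk level (L1-L2 … L5-S1) from signed
point-to-plane distances, crop a margin-enlarged disk region of interest
(ROI) per axial slice, and classify each disk as **normal**, **bulge**
or **herniation** with a cost-sensitive, subject-grouped cross-validated
classifier.  A synthetic, geometry-correct DICOM phantom generator
supplies ground truth for every stage, so the whole pipeline is testable
end to end without clinical data or trained network weights.

Intended users: medical-image-analysis researchers and engineers building
or validating automated lumbar-disk triage pipelines.

## The method

Each DICOM slice defines an affine map from fractional pixel indices to
patient coordinates (mm, LPS):

```
P(r, c) = S + c·Δc·u + r·Δr·v
```

with `S` the ImagePositionPatient, `u`/`v` the ImageOrientationPatient
direction cosines and `Δr`/`Δc` the PixelSpacing.  The plane normal is
`n = u × v`, and the *directed distance* of a vertebral-body midpoint `m`
from an axial slice plane is `d = n · (m − S)`.

An axial slice cutting through the L3-L4 disk lies below the L1–L3
midpoints and above L4–S1, so the six distances `(d_L1 … d_S1)` change
sign exactly once — between positions 3 and 4.  That unique sign change
is the level-assignment rule; when no unique strict sign change exists
(slice outside the lumbar span, or exactly through a midpoint) the level
whose midpoint-pair gap centre is nearest the plane is chosen and a
warning is emitted.

Class imbalance in the 3-class problem is handled with inverse-frequency
cost weighting, `w_k = N/(K·n_k)`; classification quality is reported as
accuracy plus one-vs-rest sensitivity and specificity from fourfold
cross-validation grouped by subject (no subject's images cross folds).

Detector and classifier backends are contracts: the shipped reference
backends (Otsu threshold + connected components; morphological shape
features + weighted multinomial logistic model) are deterministic and
designed for the phantoms, and a trained CNN backend can be plugged in
behind the same interfaces.

## Worked example

```
$ spinedx generate-phantom --out cohort --subjects 1 --seed 3
cohort/manifest.tsv
$ spinedx run cohort/phantom-000 --out report.json --seed 0
report.json
```

`report.json` contains one finding per disk level (this phantom's truth
labels are reproduced exactly; probabilities are the mean over the three
slices of each disk):

```json
{
  "findings": [
    {
      "level": "L1-L2",
      "predicted": "normal",
      "probabilities": [0.9992260056277792, 0.0007739815539610022, 1.2818259826782263e-08],
      "roi_box": [107, 93, 150, 164],
      "slice_instance_numbers": [1, 2, 3]
    },
    ...
  ],
  "provenance": {"classifier_backend": "reference-shape", "config_hash": "...", "seed": 0},
  "warnings": []
}
```

For this subject the five predicted labels — normal, normal, herniation,
herniation, herniation for L1-L2 … L5-S1 — match the generator's ground
truth, and the warnings list is empty.

The level is the disk each axial slice was geometrically assigned to,
`roi_box` is the half-open pixel box of the cropped disk region on the
central slice, and `predicted` is the argmax of the fused probabilities.
The library API mirrors the CLI: `generate_subject`, `group_axial_slices`,
`detect_vertebrae`, `locate_disk_roi`, `crop_roi`, `fourfold_cv`,
`run_pipeline` — see the module docstrings under `src/spinedx/`.

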