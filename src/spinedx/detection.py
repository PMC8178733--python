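"""Object-localization contracts: vertebral bodies and disk ROIs.

The trained detector used clinically (a region-proposal CNN) is modeled as
a backend satisfying :class:`DetectorContract` — any callable object that
maps a 2-D intensity grid to scored bounding boxes.  The shipped
:class:`ReferencePhantomDetector` is a deterministic threshold /
connected-component detector adequate for the synthetic phantoms, so the
whole pipeline is testable without trained weights.

Boxes use 0-based, half-open pixel indices: ``row_max`` / ``col_max`` are
exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .assignment import VERTEBRA_LABELS, VertebraSet
from .errors import DetectionCountError, NoDetectionError
from .geometry import bbox_midpoint_patient
from .io import DicomSlice


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel box, half-open, with an optional label and score."""

    row_min: int
    col_min: int
    row_max: int
    col_max: int
    label: str = ""
    score: float = 1.0

    def __post_init__(self) -> None:
        if self.row_min >= self.row_max or self.col_min >= self.col_max:
            raise ValueError(f"box must have positive extent: {self}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")

    @property
    def area(self) -> int:
        return (self.row_max - self.row_min) * (self.col_max - self.col_min)


@runtime_checkable
class DetectorContract(Protocol):
    """Any object mapping a 2-D intensity grid to a list of scored boxes."""

    def detect(self, image: np.ndarray) -> list[BoundingBox]: ...


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two half-open boxes, in [0, 1]."""
    ir = max(0, min(a.row_max, b.row_max) - max(a.row_min, b.row_min))
    ic = max(0, min(a.col_max, b.col_max) - max(a.col_min, b.col_min))
    inter = ir * ic
    union = a.area + b.area - inter
    return inter / union if union else 0.0


def non_max_suppression(
    boxes: Sequence[BoundingBox], iou_threshold: float = 0.5
) -> list[BoundingBox]:
    """Greedy suppression: keep the highest-score box of each overlap cluster."""
    remaining = sorted(boxes, key=lambda b: (-b.score, b.row_min, b.col_min))
    kept: list[BoundingBox] = []
    for box in remaining:
        if all(iou(box, k) < iou_threshold for k in kept):
            kept.append(box)
    return kept


@dataclass(frozen=True)
class ReferencePhantomDetector:
    """Deterministic threshold + connected-component detector for phantoms.

    Otsu's global threshold segments bright structures from background;
    connected components are filtered by area range and solidity and
    returned as tight boxes scored by their mean intensity normalized to
    the image maximum.
    """

    min_area: int = 200
    max_area: int = 6000
    min_solidity: float = 0.5

    @classmethod
    def for_vertebrae(cls) -> "ReferencePhantomDetector":
        # a lumbar vertebral body is roughly 28 x 30 mm in the sagittal plane
        return cls(min_area=200, max_area=3000, min_solidity=0.7)

    @classmethod
    def for_disks(cls) -> "ReferencePhantomDetector":
        return cls(min_area=300, max_area=8000, min_solidity=0.5)

    def detect(self, image: np.ndarray) -> list[BoundingBox]:
        image = np.asarray(image, dtype=float)
        vmax = float(image.max(initial=0.0))
        if vmax <= 0 or np.ptp(image) == 0:
            return []
        try:
            thresh = threshold_otsu(image)
        except ValueError:  # constant image slipped through
            return []
        mask = image > thresh
        boxes: list[BoundingBox] = []
        for region in regionprops(cc_label(mask), intensity_image=image):
            if not (self.min_area <= region.area <= self.max_area):
                continue
            if region.solidity < self.min_solidity:
                continue
            r0, c0, r1, c1 = region.bbox
            score = float(np.clip(region.intensity_mean / vmax, 0.0, 1.0))
            boxes.append(BoundingBox(r0, c0, r1, c1, label="component", score=score))
        return sorted(boxes, key=lambda b: (-b.score, b.row_min, b.col_min))


def detect_vertebrae(
    midsagittal: DicomSlice,
    detector: DetectorContract,
    overlap_threshold: float = 0.5,
) -> VertebraSet:
    """Locate the six vertebral bodies on the midsagittal image.

    Candidate boxes are de-duplicated by non-maximum suppression; the six
    highest-scoring survivors are labeled L1..S1 by decreasing patient-space
    z of their box midpoints (most superior first).  Labels therefore depend
    only on geometry, never on detector output order.
    """
    candidates = detector.detect(midsagittal.pixel_matrix)
    survivors = non_max_suppression(candidates, iou_threshold=overlap_threshold)
    if len(survivors) < 6:
        raise DetectionCountError(
            f"expected >= 6 vertebral-body candidates, got {len(survivors)}"
        )
    survivors = sorted(survivors, key=lambda b: -b.score)[:6]
    midpoints = [bbox_midpoint_patient(midsagittal, b) for b in survivors]
    order = np.argsort([-p[2] for p in midpoints], kind="stable")
    return VertebraSet.from_mapping(
        {VERTEBRA_LABELS[i]: midpoints[j] for i, j in enumerate(order)}
    )


def locate_disk_roi(
    axial: DicomSlice,
    detector: DetectorContract,
    score_threshold: float = 0.5,
) -> BoundingBox:
    """Locate the single disk ROI on an axial image (highest-scoring box)."""
    boxes = [b for b in detector.detect(axial.pixel_matrix) if b.score >= score_threshold]
    if not boxes:
        raise NoDetectionError(
            f"no disk ROI above score {score_threshold:g} on slice "
            f"{axial.instance_number}"
        )
    best = max(boxes, key=lambda b: b.score)
    return replace(best, label="disk")


def enlarge_box(box: BoundingBox, margin_fraction: float, shape: tuple[int, int]) -> BoundingBox:
    """Enlarge a box symmetrically by ``margin_fraction`` per side, clipped."""
    if margin_fraction < 0:
        raise ValueError("margin_fraction must be >= 0")
    dr = int(round(margin_fraction * (box.row_max - box.row_min)))
    dc = int(round(margin_fraction * (box.col_max - box.col_min)))
    return BoundingBox(
        row_min=max(0, box.row_min - dr),
        col_min=max(0, box.col_min - dc),
        row_max=min(shape[0], box.row_max + dr),
        col_max=min(shape[1], box.col_max + dc),
        label=box.label,
        score=box.score,
    )


def crop_roi(image: np.ndarray, box: BoundingBox, margin_fraction: float = 0.25,
             level=None, subject_id: str = ""):
    """Crop an ROI with an enlarged margin; surrounding structures help
    classification (e.g. spinal-canal compression), so the default keeps an
    extra 25% per side.  Returns a :class:`~spinedx.classify.RoiImage`
    recording the final (clipped) box."""
    from .classify import RoiImage  # local import avoids a cycle

    image = np.asarray(image, dtype=float)
    final = enlarge_box(box, margin_fraction, image.shape)
    pixels = image[final.row_min:final.row_max, final.col_min:final.col_max].copy()
    return RoiImage(pixels=pixels, level=level, subject_id=subject_id, box=final)
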