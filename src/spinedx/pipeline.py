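"""End-to-end orchestration: DICOM directory in, diagnosis report out.

The four stages run in order: (1) vertebral-body detection on the
midsagittal image, (2) directed-distance assignment of axial slices to
disk levels, (3) disk-ROI localization and margin-enlarged cropping per
axial slice, (4) 3-class classification per ROI.  Slice-level probability
vectors are fused into one per-disk prediction by arithmetic mean followed
by argmax.  The pipeline aborts if stage 1 fails and degrades gracefully
(slice skipped, warning recorded) when stage 3 fails on a single slice.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

from . import __version__
from .assignment import DiskLevel, group_axial_slices
from .classify import CLASS_ORDER, ClassifierContract, ClassLabel
from .detection import (
    DetectorContract,
    ReferencePhantomDetector,
    crop_roi,
    detect_vertebrae,
    locate_disk_roi,
)
from .errors import NoDetectionError, PipelineStageError, SpinedxError
from .io import SeriesSet, load_series, select_midsagittal

#: number of synthetic training subjects per level for the default backend
_DEFAULT_TRAIN_PER_LEVEL = 24


@dataclass
class PipelineConfig:
    """Tunable pipeline parameters and pluggable backends.

    When ``classifier`` is None, a reference shape classifier is trained on
    an internally generated, class-balanced synthetic ROI set derived from
    ``seed`` — fully deterministic, adequate for phantom data.
    """

    margin_fraction: float = 0.25
    score_threshold: float = 0.5
    overlap_threshold: float = 0.5
    plausibility_mm: float = 30.0
    seed: int = 0
    vertebra_detector: DetectorContract | None = None
    disk_detector: DetectorContract | None = None
    classifier: ClassifierContract | None = None
    detector_backend: str = "reference-phantom"
    classifier_backend: str = "reference-shape"

    def __post_init__(self) -> None:
        if not 0 <= self.margin_fraction <= 2:
            raise ValueError("margin_fraction must lie in [0, 2]")
        if not 0 <= self.score_threshold <= 1 or not 0 <= self.overlap_threshold <= 1:
            raise ValueError("score and overlap thresholds must lie in [0, 1]")
        if self.plausibility_mm <= 0:
            raise ValueError("plausibility_mm must be positive")

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "margin_fraction": self.margin_fraction,
                "score_threshold": self.score_threshold,
                "overlap_threshold": self.overlap_threshold,
                "plausibility_mm": self.plausibility_mm,
                "seed": self.seed,
                "detector_backend": self.detector_backend,
                "classifier_backend": self.classifier_backend,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class LevelFinding:
    """One per-disk row of the report."""

    level: DiskLevel
    predicted: ClassLabel
    probabilities: list[float]  # order normal, bulge, herniation; sums to 1
    slice_instance_numbers: list[int]
    roi_box: list[int] | None  # (row_min, col_min, row_max, col_max), half-open


@dataclass
class DiagnosisReport:
    """Structured per-subject diagnosis with full provenance."""

    subject_id: str
    findings: list[LevelFinding] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def _default_classifier(seed: int) -> ClassifierContract:
    from .classify import reference_shape_classifier
    from .phantom import generate_roi_dataset

    rois = generate_roi_dataset(n_per_level=_DEFAULT_TRAIN_PER_LEVEL, seed=seed)
    clf = reference_shape_classifier()
    clf.fit(rois, np.ones(3), seed)
    return clf


def run_pipeline(
    source: Union[str, Path, SeriesSet], config: PipelineConfig | None = None
) -> DiagnosisReport:
    """Run all four stages on a DICOM directory (or an in-memory SeriesSet)."""
    config = config or PipelineConfig()
    vertebra_detector = config.vertebra_detector or ReferencePhantomDetector.for_vertebrae()
    disk_detector = config.disk_detector or ReferencePhantomDetector.for_disks()
    classifier = config.classifier or _default_classifier(config.seed)

    captured: list[str] = []
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always")

        if isinstance(source, SeriesSet):
            series = source
        else:
            try:
                series = load_series(source)
            except SpinedxError as exc:
                raise PipelineStageError("load-series", str(exc)) from exc

        try:
            midsagittal = select_midsagittal(series.sagittal_slices)
            vertebrae = detect_vertebrae(
                midsagittal, vertebra_detector, overlap_threshold=config.overlap_threshold
            )
        except SpinedxError as exc:
            raise PipelineStageError("vertebra-detection", str(exc)) from exc

        grouped = group_axial_slices(
            series, vertebrae, plausibility_threshold_mm=config.plausibility_mm
        )
        by_instance = {s.instance_number: s for s in series.axial_slices}

        findings: list[LevelFinding] = []
        for level, assignments in grouped.items():
            probs: list[np.ndarray] = []
            used: list[int] = []
            central_box = None
            central_gap = np.inf
            for a in assignments:
                axial = by_instance[a.slice_ref]
                try:
                    box = locate_disk_roi(
                        axial, disk_detector, score_threshold=config.score_threshold
                    )
                except NoDetectionError as exc:
                    captured.append(f"roi-localization: {exc}")
                    continue
                roi = crop_roi(
                    axial.pixel_matrix, box, config.margin_fraction,
                    level=level, subject_id=series.subject_id,
                )
                probs.append(np.asarray(classifier.predict_proba(roi), dtype=float))
                used.append(a.slice_ref)
                if abs(a.gap_center) < central_gap:
                    central_gap = abs(a.gap_center)
                    central_box = roi.box
            if not probs:
                captured.append(
                    f"classification: no usable ROI for level {level.value}; level omitted"
                )
                continue
            mean_p = np.mean(probs, axis=0)
            mean_p = mean_p / mean_p.sum()
            findings.append(
                LevelFinding(
                    level=level,
                    predicted=CLASS_ORDER[int(np.argmax(mean_p))],
                    probabilities=[float(p) for p in mean_p],
                    slice_instance_numbers=used,
                    roi_box=[
                        central_box.row_min, central_box.col_min,
                        central_box.row_max, central_box.col_max,
                    ] if central_box else None,
                )
            )
    captured = [f"{w.category.__name__}: {w.message}" for w in rec] + captured

    return DiagnosisReport(
        subject_id=series.subject_id,
        findings=findings,
        warnings=captured,
        provenance={
            "package": "spinedx",
            "version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "detector_backend": config.detector_backend,
            "classifier_backend": config.classifier_backend,
        },
    )


def serialize_report(report: DiagnosisReport) -> str:
    """Serialize a report to canonical JSON (stable key order, round-trippable)."""
    doc = {
        "subject_id": report.subject_id,
        "findings": [
            {
                "level": f.level.value,
                "predicted": f.predicted.value,
                "probabilities": f.probabilities,
                "slice_instance_numbers": f.slice_instance_numbers,
                "roi_box": f.roi_box,
            }
            for f in report.findings
        ],
        "warnings": report.warnings,
        "provenance": report.provenance,
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def parse_report(text: str) -> DiagnosisReport:
    """Inverse of :func:`serialize_report`."""
    doc = json.loads(text)
    return DiagnosisReport(
        subject_id=doc["subject_id"],
        findings=[
            LevelFinding(
                level=DiskLevel.from_string(f["level"]),
                predicted=ClassLabel.from_string(f["predicted"]),
                probabilities=list(f["probabilities"]),
                slice_instance_numbers=list(f["slice_instance_numbers"]),
                roi_box=list(f["roi_box"]) if f["roi_box"] is not None else None,
            )
            for f in doc["findings"]
        ],
        warnings=list(doc["warnings"]),
        provenance=dict(doc["provenance"]),
    )
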