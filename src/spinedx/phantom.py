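"""Synthetic lumbar MR subjects with full ground truth.

The generator builds a patient-space spine model — six bright vertebral
bodies (L1..S1) stacked along a smoothly curved (lordotic) axis — and
renders geometry-consistent sagittal and axial DICOM slices from it:

* sagittal slices show the six vertebral bodies as bright rectangles with
  dimmer disks between them;
* axial slices are placed strictly between adjacent vertebral midpoints
  (``slices_per_disk`` per disk, optionally tilted per disk) and show one
  disk cross-section whose morphology encodes the class: a plain ellipse
  (normal), a wide concentric posterior expansion (bulge) or a narrow focal
  posterior lobe (herniation);
* all DICOM geometry tags (position, orientation, spacing) are written
  consistently with the 3-D model, so every downstream stage can be checked
  against the generator's ground truth.

Per-subject randomness (curvature amplitude, per-disk tilt, shape jitter,
noise) is drawn from a seeded generator, so a subject is bit-reproducible
from its seed.  Disk morphologies are parametric 2-D shapes chosen for
controllable separability, not anatomical simulations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np

from .assignment import DISK_LEVELS, VERTEBRA_LABELS, DiskLevel, VertebraSet
from .classify import CLASS_ORDER, CLINICAL_CLASS_COUNTS, ClassLabel, RoiImage
from .detection import BoundingBox
from .errors import InvalidSpecError
from .io import DicomSlice, SeriesSet, write_slice

#: per-level class priors (normal, bulge, herniation) derived from the
#: clinical cohort counts in :data:`~spinedx.classify.CLINICAL_CLASS_COUNTS`
DEFAULT_CLASS_PRIORS: dict[DiskLevel, np.ndarray] = {
    lvl: np.asarray(c, dtype=float) / sum(c) for lvl, c in CLINICAL_CLASS_COUNTS.items()
}

SeedLike = Union[int, Sequence[int], np.random.SeedSequence]

# fixed rendering constants (mm); pixel spacing is 1 mm in both planes
_VERTEBRA_WIDTH = 40.0   # lateral (x) extent of a vertebral body
_VERTEBRA_DEPTH = 30.0   # antero-posterior (y) extent
_DISK_HALF_WIDTH = 15.0  # lateral half-extent of the disk in sagittal view
_SAGITTAL_SPACING = 5.0  # mm between sagittal slices
_DISK_A = 22.0           # axial disk semi-axis, lateral (mm)
_DISK_B = 14.0           # axial disk semi-axis, antero-posterior (mm)
_INTENSITY_VERTEBRA = 1.0
_INTENSITY_DISK_SAG = 0.15
_INTENSITY_DISK_AX = 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for the synthetic cohort.

    ``curvature_amplitude`` and ``axial_tilt_degrees`` are *ranges*: each
    subject draws its lordosis bow uniformly from ``[0, curvature_amplitude]``
    mm and each disk draws its axial tilt uniformly from
    ``±axial_tilt_degrees``.  ``noise_sd`` is relative to the foreground
    signal level (1.0).
    """

    n_subjects: int = 1
    vertebra_height: float = 28.0
    disk_height: float = 10.0
    curvature_amplitude: float = 15.0
    axial_tilt_degrees: float = 12.0
    slices_per_disk: int = 3
    sagittal_slice_count: int = 11
    image_size: int = 256
    noise_sd: float = 0.02
    class_assignment: Union[str, Mapping[DiskLevel, ClassLabel]] = "sample-from-priors"
    class_priors: Mapping[DiskLevel, np.ndarray] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PRIORS)
    )
    include_flanking_slices: bool = False  # extra slices beyond L1 / S1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.vertebra_height, self.disk_height) <= 0:
            raise InvalidSpecError("vertebra_height and disk_height must be positive")
        if self.n_subjects < 1 or self.slices_per_disk < 1:
            raise InvalidSpecError("n_subjects and slices_per_disk must be >= 1")
        if self.sagittal_slice_count < 1 or self.sagittal_slice_count % 2 == 0:
            raise InvalidSpecError("sagittal_slice_count must be a positive odd integer")
        if self.curvature_amplitude < 0 or self.axial_tilt_degrees < 0:
            raise InvalidSpecError("curvature and tilt ranges must be >= 0")
        if self.image_size < 64:
            raise InvalidSpecError("image_size must be >= 64 pixels")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if isinstance(self.class_assignment, str):
            if self.class_assignment != "sample-from-priors":
                raise InvalidSpecError(
                    "class_assignment must be a per-level mapping or 'sample-from-priors'"
                )
            for lvl in DISK_LEVELS:
                p = np.asarray(self.class_priors[lvl], dtype=float)
                if p.shape != (3,) or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
                    raise InvalidSpecError(f"class priors for {lvl.value} must sum to 1")
        else:
            missing = [l.value for l in DISK_LEVELS if l not in self.class_assignment]
            if missing:
                raise InvalidSpecError(f"class_assignment missing levels {missing}")


@dataclass
class PhantomTruth:
    """Ground truth for one synthetic subject."""

    vertebra_midpoints: VertebraSet
    slice_levels: dict[int, DiskLevel]          # axial instance_number -> level
    roi_boxes: dict[int, BoundingBox]           # axial instance_number -> truth box
    labels: dict[DiskLevel, ClassLabel]         # per-level disk condition


# ---------------------------------------------------------------------------
# geometry model


def _vertebra_centers(spec: PhantomSpec, curvature_mm: float) -> np.ndarray:
    """Centres of L1..S1 (rows), L1 most superior, bowed anteriorly (-y)."""
    pitch = spec.vertebra_height + spec.disk_height
    centers = np.zeros((6, 3))
    for i in range(6):
        t = i / 5.0
        centers[i, 1] = -curvature_mm * np.sin(np.pi * t)
        centers[i, 2] = (5 - i) * pitch
    return centers


def _fill_rect(img: np.ndarray, r_lo: float, r_hi: float, c_lo: float, c_hi: float,
               value: float) -> None:
    n = img.shape[0]
    r0 = int(np.clip(round(r_lo), 0, n))
    r1 = int(np.clip(round(r_hi), 0, n))
    c0 = int(np.clip(round(c_lo), 0, n))
    c1 = int(np.clip(round(c_hi), 0, n))
    if r0 < r1 and c0 < c1:
        img[r0:r1, c0:c1] = value


def _disk_axes(rng: np.random.Generator, scale: float = 1.0) -> tuple[float, float]:
    """Disk semi-axes: a common ±10% size factor plus ±1% per-axis jitter."""
    s = 1.0 + rng.uniform(-0.1, 0.1)
    a = _DISK_A * scale * s * (1.0 + rng.uniform(-0.01, 0.01))
    b = _DISK_B * scale * s * (1.0 + rng.uniform(-0.01, 0.01))
    return a, b


def _morphology_params(label: ClassLabel, rng: np.random.Generator):
    """Posterior-margin deformation (amplitude, width) for each class.

    Positive amplitude is a Gaussian-profile radial *bump* on the posterior
    margin: broad and posterior-directed for bulge, narrow for the focal
    herniation lobe; the normal disk is a plain ellipse (amplitude 0).
    """
    if label is ClassLabel.NORMAL:
        return 0.0, 1.0
    if label is ClassLabel.BULGE:
        return float(rng.uniform(0.40, 0.55)), float(rng.uniform(0.7, 0.9))
    return float(rng.uniform(0.80, 1.00)), float(rng.uniform(0.20, 0.30))


def _draw_disk(canvas: np.ndarray, center_rc: tuple[float, float],
               a: float, b: float, amp: float, sigma: float,
               intensity: float) -> BoundingBox:
    """Draw one axial disk cross-section; returns its tight truth box.

    The outline is an ellipse (semi-axes ``a`` lateral / columns, ``b``
    antero-posterior / rows).  For ``amp >= 0`` a Gaussian radial bump of
    relative amplitude ``amp`` and angular width ``sigma`` (radians) is
    added at the posterior margin (increasing row index); for ``amp < 0``
    a central posterior concavity of relative depth ``|amp|`` and lateral
    width ``sigma`` (in units of ``a``) is carved out instead.
    """
    rows, cols = np.indices(canvas.shape)
    u = (cols - center_rc[1]) / a
    v = (rows - center_rc[0]) / b
    rho = np.hypot(u, v)
    if amp >= 0:
        phi = np.arctan2(v, u)
        bump = amp * np.exp(-0.5 * ((phi - np.pi / 2) / sigma) ** 2)
        mask = rho <= 1.0 + bump
    else:
        mask = rho <= 1.0
        v_boundary = np.sqrt(np.clip(1.0 - u**2, 0.0, None))
        carve = v > v_boundary + amp * np.exp(-0.5 * (u / sigma) ** 2)
        mask &= ~carve
    canvas[mask] = intensity
    rr = np.flatnonzero(mask.any(axis=1))
    cc = np.flatnonzero(mask.any(axis=0))
    return BoundingBox(int(rr[0]), int(cc[0]), int(rr[-1]) + 1, int(cc[-1]) + 1,
                       label="disk", score=1.0)


def _sample_labels(
    spec: PhantomSpec, rng: np.random.Generator
) -> dict[DiskLevel, ClassLabel]:
    if isinstance(spec.class_assignment, Mapping):
        return {lvl: spec.class_assignment[lvl] for lvl in DISK_LEVELS}
    labels: dict[DiskLevel, ClassLabel] = {}
    for lvl in DISK_LEVELS:
        p = np.asarray(spec.class_priors[lvl], dtype=float)
        labels[lvl] = CLASS_ORDER[int(rng.choice(3, p=p / p.sum()))]
    return labels


# ---------------------------------------------------------------------------
# subject generation


def generate_subject(
    spec: PhantomSpec, subject_seed: SeedLike, subject_id: str = "phantom-000"
) -> tuple[SeriesSet, PhantomTruth]:
    """Generate one synthetic subject: sagittal + axial stacks and truth.

    Bit-reproducible for a fixed ``subject_seed``.
    """
    rng = np.random.default_rng(subject_seed)
    n = spec.image_size
    half = n / 2.0
    curvature = float(rng.uniform(0.0, spec.curvature_amplitude))
    tilts_deg = rng.uniform(-spec.axial_tilt_degrees, spec.axial_tilt_degrees, size=5)
    centers = _vertebra_centers(spec, curvature)
    vertebrae = VertebraSet(centers)

    # ---- sagittal stack: planes x = const, rows toward inferior (-z),
    # columns toward posterior (+y)
    z0 = centers[0, 2] + spec.vertebra_height / 2.0 + 21.0  # patient z of row 0
    y0 = -64.0                                              # patient y of column 0
    k = spec.sagittal_slice_count
    sag_series_id = f"{subject_id}-sag"
    sagittal: list[DicomSlice] = []
    hv = spec.vertebra_height / 2.0
    for j in range(k):
        x = (j - (k - 1) / 2.0) * _SAGITTAL_SPACING
        img = np.zeros((n, n))
        if abs(x) <= _VERTEBRA_WIDTH / 2.0:
            for i in range(6):
                cy, cz = centers[i, 1], centers[i, 2]
                _fill_rect(
                    img,
                    z0 - (cz + hv), z0 - (cz - hv),
                    (cy - _VERTEBRA_DEPTH / 2.0) - y0, (cy + _VERTEBRA_DEPTH / 2.0) - y0,
                    _INTENSITY_VERTEBRA,
                )
        if abs(x) <= _DISK_HALF_WIDTH:
            for i in range(5):
                gy = 0.5 * (centers[i, 1] + centers[i + 1, 1])
                gz = 0.5 * (centers[i, 2] + centers[i + 1, 2])
                hd = spec.disk_height / 2.0
                _fill_rect(
                    img,
                    z0 - (gz + hd), z0 - (gz - hd),
                    (gy - _VERTEBRA_DEPTH / 2.0) - y0, (gy + _VERTEBRA_DEPTH / 2.0) - y0,
                    _INTENSITY_DISK_SAG,
                )
        if spec.noise_sd > 0:
            img = np.clip(img + rng.normal(0.0, spec.noise_sd, img.shape), 0.0, None)
        sagittal.append(
            DicomSlice(
                pixel_matrix=img,
                image_position=np.array([x, y0, z0]),
                row_direction=np.array([0.0, 1.0, 0.0]),
                column_direction=np.array([0.0, 0.0, -1.0]),
                pixel_spacing=(1.0, 1.0),
                instance_number=j + 1,
                series_id=sag_series_id,
            )
        )

    # ---- axial stack: slices_per_disk planes strictly between each pair of
    # adjacent midpoints, tilted about the x axis per disk
    labels = _sample_labels(spec, rng)
    ax_series_id = f"{subject_id}-ax"
    axial: list[DicomSlice] = []
    slice_levels: dict[int, DiskLevel] = {}
    roi_boxes: dict[int, BoundingBox] = {}
    instance = 0

    def _axial_plane_points() -> list[tuple[np.ndarray, float, DiskLevel]]:
        points = []
        if spec.include_flanking_slices:
            top = centers[0] + np.array([0, 0, spec.vertebra_height / 2.0 + 5.0])
            points.append((top, 0.0, DiskLevel.L1_L2))
        spd = spec.slices_per_disk
        offsets = np.linspace((spd - 1) / 2.0, -(spd - 1) / 2.0, spd)
        offsets = offsets * (spec.disk_height / spd)
        for i in range(5):
            gap_center = 0.5 * (centers[i] + centers[i + 1])
            u = centers[i] - centers[i + 1]
            u = u / np.linalg.norm(u)
            for off in offsets:
                points.append((gap_center + off * u, tilts_deg[i], DISK_LEVELS[i]))
        if spec.include_flanking_slices:
            bottom = centers[5] - np.array([0, 0, spec.vertebra_height / 2.0 + 5.0])
            points.append((bottom, 0.0, DiskLevel.L5_S1))
        return points

    for point, tilt_deg, level in _axial_plane_points():
        instance += 1
        theta = np.deg2rad(tilt_deg)
        row_dir = np.array([1.0, 0.0, 0.0])
        col_dir = np.array([0.0, np.cos(theta), np.sin(theta)])
        position = point - half * row_dir - half * col_dir
        img = np.zeros((n, n))
        a, b = _disk_axes(rng)
        amp, sigma = _morphology_params(labels[level], rng)
        box = _draw_disk(img, (half, half), a, b, amp, sigma, _INTENSITY_DISK_AX)
        if spec.noise_sd > 0:
            img = np.clip(img + rng.normal(0.0, spec.noise_sd, img.shape), 0.0, None)
        axial.append(
            DicomSlice(
                pixel_matrix=img,
                image_position=position,
                row_direction=row_dir,
                column_direction=col_dir,
                pixel_spacing=(1.0, 1.0),
                instance_number=instance,
                series_id=ax_series_id,
            )
        )
        slice_levels[instance] = level
        roi_boxes[instance] = box

    series = SeriesSet(subject_id=subject_id, sagittal_slices=sagittal, axial_slices=axial)
    truth = PhantomTruth(
        vertebra_midpoints=vertebrae,
        slice_levels=slice_levels,
        roi_boxes=roi_boxes,
        labels=labels,
    )
    return series, truth


def generate_cohort(spec: PhantomSpec) -> list[tuple[SeriesSet, PhantomTruth]]:
    """Generate ``spec.n_subjects`` subjects with seeds derived from ``spec.seed``."""
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_subjects)
    return [
        generate_subject(spec, child, subject_id=f"phantom-{i:03d}")
        for i, child in enumerate(children)
    ]


# ---------------------------------------------------------------------------
# ROI-only datasets for the classifier harness


def generate_roi_dataset(
    n_per_level: int,
    seed: int,
    scheme: str = "balanced",
    image_side: int = 96,
    noise_sd: float = 0.02,
    priors: Mapping[DiskLevel, np.ndarray] | None = None,
) -> list[RoiImage]:
    """Labeled ROI images rendered directly (no full DICOM subject).

    Each synthetic subject contributes one ROI per disk level.  With
    ``scheme='balanced'`` labels cycle deterministically so each level gets
    an equal class split; with ``scheme='priors'`` labels are sampled from
    the per-level priors (clinical cohort proportions by default).
    """
    if scheme not in ("balanced", "priors"):
        raise ValueError("scheme must be 'balanced' or 'priors'")
    priors = dict(priors or DEFAULT_CLASS_PRIORS)
    rng = np.random.default_rng(seed)
    rois: list[RoiImage] = []
    scale = image_side / 96.0
    for s in range(n_per_level):
        subject = f"s{s:04d}"
        for j, level in enumerate(DISK_LEVELS):
            if scheme == "balanced":
                label = CLASS_ORDER[(s + j) % 3]
            else:
                p = np.asarray(priors[level], dtype=float)
                label = CLASS_ORDER[int(rng.choice(3, p=p / p.sum()))]
            img = np.zeros((image_side, image_side))
            a, b = _disk_axes(rng, scale=scale)
            amp, sigma = _morphology_params(label, rng)
            box = _draw_disk(img, (image_side / 2.0, image_side / 2.0),
                             a, b, amp, sigma, _INTENSITY_DISK_AX)
            if noise_sd > 0:
                img = np.clip(img + rng.normal(0.0, noise_sd, img.shape), 0.0, None)
            rois.append(
                RoiImage(pixels=img, level=level, truth_label=label,
                         subject_id=subject, box=box)
            )
    return rois


# ---------------------------------------------------------------------------
# on-disk cohorts (DICOM files + structured-text sidecars)


def _truth_to_dict(truth: PhantomTruth) -> dict:
    return {
        "vertebra_midpoints": {
            lab: [float(v) for v in truth.vertebra_midpoints.midpoint(lab)]
            for lab in VERTEBRA_LABELS
        },
        "slice_levels": {str(k): v.value for k, v in truth.slice_levels.items()},
        "roi_boxes": {
            str(k): [b.row_min, b.col_min, b.row_max, b.col_max]
            for k, b in truth.roi_boxes.items()
        },
        "labels": {lvl.value: lab.value for lvl, lab in truth.labels.items()},
    }


def _truth_from_dict(d: dict) -> PhantomTruth:
    return PhantomTruth(
        vertebra_midpoints=VertebraSet.from_mapping(d["vertebra_midpoints"]),
        slice_levels={int(k): DiskLevel.from_string(v) for k, v in d["slice_levels"].items()},
        roi_boxes={
            int(k): BoundingBox(*v, label="disk") for k, v in d["roi_boxes"].items()
        },
        labels={
            DiskLevel.from_string(k): ClassLabel.from_string(v)
            for k, v in d["labels"].items()
        },
    )


def write_subject(series: SeriesSet, truth: PhantomTruth, out_dir: str | Path) -> Path:
    """Write one subject as DICOM Part-10 files plus a JSON truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for s in series.sagittal_slices:
        write_slice(s, out_dir / f"sag_{s.instance_number:03d}.dcm", series.subject_id)
    for s in series.axial_slices:
        write_slice(s, out_dir / f"ax_{s.instance_number:03d}.dcm", series.subject_id)
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(_truth_to_dict(truth), indent=2, sort_keys=True))
    return truth_path


def load_truth(path: str | Path) -> PhantomTruth:
    """Read a truth sidecar written by :func:`write_subject`."""
    return _truth_from_dict(json.loads(Path(path).read_text()))


def write_cohort(spec: PhantomSpec, out_dir: str | Path) -> Path:
    """Write a cohort to disk; returns the path of the tab-separated manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = ["subject_id\tdirectory\ttruth"]
    for series, truth in generate_cohort(spec):
        sub_dir = out_dir / series.subject_id
        truth_path = write_subject(series, truth, sub_dir)
        rows.append(f"{series.subject_id}\t{sub_dir.name}\t{sub_dir.name}/{truth_path.name}")
    manifest = out_dir / "manifest.tsv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest


def write_roi_dataset(rois: Sequence[RoiImage], out_dir: str | Path) -> Path:
    """Write ROI images (.npy) plus a tab-separated manifest; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = ["path\tsubject_id\tlevel\tlabel"]
    for i, roi in enumerate(rois):
        name = f"roi_{i:05d}.npy"
        np.save(out_dir / name, roi.pixels)
        label = roi.truth_label.value if roi.truth_label else ""
        level = roi.level.value if roi.level else ""
        rows.append(f"{name}\t{roi.subject_id}\t{level}\t{label}")
    manifest = out_dir / "manifest.tsv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest


def load_roi_manifest(manifest_path: str | Path) -> list[RoiImage]:
    """Read an ROI dataset manifest written by :func:`write_roi_dataset`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    lines = manifest_path.read_text().strip().splitlines()
    header = lines[0].split("\t")
    if header != ["path", "subject_id", "level", "label"]:
        raise ValueError(f"malformed ROI manifest {manifest_path}: header {header}")
    rois = []
    for line in lines[1:]:
        path, subject, level, label = line.split("\t")
        rois.append(
            RoiImage(
                pixels=np.load(base / path),
                level=DiskLevel.from_string(level) if level else None,
                truth_label=ClassLabel.from_string(label) if label else None,
                subject_id=subject,
            )
        )
    return rois
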