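"""Reading, validating and grouping DICOM MR slices.

Conventions fixed here and used everywhere else in the package:

* patient coordinates are DICOM LPS (x toward patient left, y toward
  posterior, z toward superior), in millimetres;
* pixel indices are 0-based ``(row, column)``;
* ``row_direction`` is the unit vector along which the *column index*
  increases (the first ImageOrientationPatient triplet, i.e. the direction
  of a row), ``column_direction`` the one along which the *row index*
  increases (the second triplet);
* ``pixel_spacing`` is ``(between-rows, between-columns)`` mm, matching the
  DICOM PixelSpacing tag order.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.errors import InvalidDicomError
from pydicom.uid import ExplicitVRLittleEndian, MRImageStorage

from .errors import EmptySeriesError, MissingTagError

logger = logging.getLogger("spinedx")

_UNIT_TOL = 1e-6

#: mandatory geometry tags; everything else (SliceThickness, ...) is optional
MANDATORY_TAGS = (
    "ImagePositionPatient",
    "ImageOrientationPatient",
    "PixelSpacing",
    "InstanceNumber",
    "SeriesInstanceUID",
)


def _as_unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float).reshape(3)
    n = float(np.linalg.norm(v))
    if abs(n - 1.0) > _UNIT_TOL:
        raise ValueError(f"{name} is not a unit vector (|v| = {n:.9f})")
    return v


@dataclass(frozen=True)
class DicomSlice:
    """One MR slice with its pixel matrix and full spatial tags.

    Parameters
    ----------
    pixel_matrix
        2-D intensity grid, ``(rows, columns)``, arbitrary MR units.
    image_position
        Patient-space position (mm, LPS) of the centre of pixel ``(0, 0)``.
    row_direction, column_direction
        Orthonormal in-plane direction vectors (see module docstring).
    pixel_spacing
        ``(between-rows, between-columns)`` spacing in mm.
    instance_number
        Positive DICOM InstanceNumber.
    series_id
        Opaque series identifier (SeriesInstanceUID).
    """

    pixel_matrix: np.ndarray
    image_position: np.ndarray
    row_direction: np.ndarray
    column_direction: np.ndarray
    pixel_spacing: tuple[float, float]
    instance_number: int
    series_id: str

    def __post_init__(self) -> None:
        m = np.asarray(self.pixel_matrix, dtype=float)
        if m.ndim != 2 or m.size == 0:
            raise ValueError("pixel_matrix must be a non-empty 2-D array")
        object.__setattr__(self, "pixel_matrix", m)
        object.__setattr__(
            self, "image_position", np.asarray(self.image_position, dtype=float).reshape(3)
        )
        r = _as_unit(self.row_direction, "row_direction")
        c = _as_unit(self.column_direction, "column_direction")
        if abs(float(np.dot(r, c))) > _UNIT_TOL:
            raise ValueError("row_direction and column_direction are not orthogonal")
        object.__setattr__(self, "row_direction", r)
        object.__setattr__(self, "column_direction", c)
        dr, dc = (float(s) for s in self.pixel_spacing)
        if dr <= 0 or dc <= 0:
            raise ValueError("pixel_spacing components must be positive")
        object.__setattr__(self, "pixel_spacing", (dr, dc))
        if int(self.instance_number) <= 0:
            raise ValueError("instance_number must be a positive integer")
        object.__setattr__(self, "instance_number", int(self.instance_number))

    @property
    def normal(self) -> np.ndarray:
        """Unit plane normal, ``row_direction x column_direction``."""
        n = np.cross(self.row_direction, self.column_direction)
        return n / np.linalg.norm(n)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixel_matrix.shape  # type: ignore[return-value]


@dataclass
class SeriesSet:
    """The sagittal and axial slice stacks of one subject."""

    subject_id: str
    sagittal_slices: list[DicomSlice] = field(default_factory=list)
    axial_slices: list[DicomSlice] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("sagittal_slices", "axial_slices"):
            slices: list[DicomSlice] = getattr(self, name)
            nums = [s.instance_number for s in slices]
            if any(b <= a for a, b in zip(nums, nums[1:])):
                raise ValueError(f"{name} must be strictly increasing in instance_number")
            if len({s.series_id for s in slices}) > 1:
                raise ValueError(f"{name} mixes more than one series_id")


def classify_orientation(s: DicomSlice) -> str:
    """Label a slice ``sagittal``, ``axial`` or ``coronal`` by its plane normal.

    The dominant absolute component of ``row_direction x column_direction``
    decides: x -> sagittal, y -> coronal, z -> axial.  An exact tie involving
    the z component is broken toward axial (deterministic, unreachable for
    realistic geometry).
    """
    a = np.abs(s.normal)
    if a[2] >= max(a[0], a[1]) - 1e-12:
        return "axial"
    return "sagittal" if a[0] >= a[1] else "coronal"


def select_midsagittal(sagittal_slices: Sequence[DicomSlice]) -> DicomSlice:
    """Pick the sagittal slice closest to the stack centroid along the normal.

    Ties (e.g. an even symmetric stack) resolve to the lower instance_number.
    """
    if not sagittal_slices:
        raise EmptySeriesError("cannot select a midsagittal slice from an empty list")
    normals = np.stack([s.normal for s in sagittal_slices])
    n_mean = normals.mean(axis=0)
    n_mean /= np.linalg.norm(n_mean)
    origins = np.stack([s.image_position for s in sagittal_slices])
    centroid = origins.mean(axis=0)
    score = np.abs((origins - centroid) @ n_mean)
    best = score.min()
    candidates = [s for s, sc in zip(sagittal_slices, score) if sc <= best + 1e-9]
    return min(candidates, key=lambda s: s.instance_number)


def _slice_from_dataset(ds: Dataset, path: Path) -> DicomSlice:
    for tag in MANDATORY_TAGS:
        if getattr(ds, tag, None) is None:
            raise MissingTagError(str(path), tag)
    if not hasattr(ds, "PixelData"):
        raise MissingTagError(str(path), "PixelData")
    pix = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    pix = pix * slope + intercept
    iop = np.asarray(ds.ImageOrientationPatient, dtype=float)
    return DicomSlice(
        pixel_matrix=pix,
        image_position=np.asarray(ds.ImagePositionPatient, dtype=float),
        row_direction=iop[:3],
        column_direction=iop[3:],
        pixel_spacing=(float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1])),
        instance_number=int(ds.InstanceNumber),
        series_id=str(ds.SeriesInstanceUID),
    )


def load_series(directory_path: str | Path, subject_id: str | None = None) -> SeriesSet:
    """Load a directory of DICOM files and partition into sagittal and axial stacks.

    Slices are grouped by SeriesInstanceUID; for each of the sagittal and
    axial orientations the largest series is kept (others, and all coronal
    or otherwise oriented slices, are excluded and logged).  Raises
    :class:`MissingTagError` on files missing geometry tags and
    :class:`EmptySeriesError` when either partition ends up empty.
    """
    directory_path = Path(directory_path)
    patient_ids: set[str] = set()
    by_series: dict[str, list[DicomSlice]] = {}
    for path in sorted(directory_path.iterdir()):
        if not path.is_file():
            continue
        try:
            ds = pydicom.dcmread(path)
        except InvalidDicomError:
            logger.info("skipping non-DICOM file %s", path)
            continue
        s = _slice_from_dataset(ds, path)
        pid = str(getattr(ds, "PatientID", "") or "")
        if pid:
            patient_ids.add(pid)
        by_series.setdefault(s.series_id, []).append(s)

    partitions: dict[str, list[list[DicomSlice]]] = {"sagittal": [], "axial": []}
    for sid, slices in by_series.items():
        labels = {classify_orientation(s) for s in slices}
        if len(labels) != 1:
            logger.warning("series %s mixes orientations %s; excluded", sid, sorted(labels))
            continue
        label = labels.pop()
        if label in partitions:
            partitions[label].append(slices)
        else:
            logger.info("excluding %d slice(s) of series %s with orientation %s",
                        len(slices), sid, label)

    chosen: dict[str, list[DicomSlice]] = {}
    for label, groups in partitions.items():
        if not groups:
            raise EmptySeriesError(
                f"directory {directory_path} contains no {label} series"
            )
        groups.sort(key=len, reverse=True)
        for extra in groups[1:]:
            logger.warning("excluding secondary %s series %s (%d slices)",
                           label, extra[0].series_id, len(extra))
        chosen[label] = sorted(groups[0], key=lambda s: s.instance_number)

    if subject_id is None:
        subject_id = patient_ids.pop() if len(patient_ids) == 1 else directory_path.name
    return SeriesSet(
        subject_id=subject_id,
        sagittal_slices=chosen["sagittal"],
        axial_slices=chosen["axial"],
    )


# ---------------------------------------------------------------------------
# writing (used by the phantom generator)

_UID_ROOT = "1.2.826.0.1.3680043.8.498"  # pydicom's public test root

_PIXEL_SCALE = 1000.0  # stored uint16 = intensity * scale


def deterministic_uid(*parts: object) -> str:
    """A DICOM UID derived deterministically from the given parts."""
    digest = hashlib.sha256("/".join(str(p) for p in parts).encode()).hexdigest()
    return f"{_UID_ROOT}.{int(digest[:30], 16) % 10**30}"


def _as_uid(series_id: str) -> str:
    """Use the series_id as-is when it is a legal UID, else derive one."""
    if series_id and all(c in "0123456789." for c in series_id) and len(series_id) <= 64:
        return series_id
    return deterministic_uid("series", series_id)


def write_slice(s: DicomSlice, path: str | Path, patient_id: str) -> None:
    """Write one slice as a standard Part-10 MR Image Storage file."""
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = MRImageStorage
    meta.MediaStorageSOPInstanceUID = deterministic_uid(s.series_id, s.instance_number)
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = MRImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "MR"
    ds.PatientID = patient_id
    ds.PatientName = patient_id
    ds.StudyInstanceUID = deterministic_uid(patient_id, "study")
    ds.SeriesInstanceUID = _as_uid(s.series_id)
    ds.InstanceNumber = s.instance_number
    ds.ImagePositionPatient = [float(v) for v in s.image_position]
    ds.ImageOrientationPatient = [
        float(v) for v in np.concatenate([s.row_direction, s.column_direction])
    ]
    ds.PixelSpacing = [float(s.pixel_spacing[0]), float(s.pixel_spacing[1])]
    ds.Rows, ds.Columns = (int(v) for v in s.pixel_matrix.shape)
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = 1.0 / _PIXEL_SCALE
    ds.RescaleIntercept = 0.0
    stored = np.clip(np.round(s.pixel_matrix * _PIXEL_SCALE), 0, 65535).astype(np.uint16)
    ds.PixelData = stored.tobytes()
    ds.save_as(path, enforce_file_format=True)
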