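"""Pixel <-> patient coordinate mapping and signed plane distances.

This is the mathematical core of the slice-to-disk-level assignment: every
slice defines an affine map from fractional ``(row, column)`` pixel indices
to 3-D LPS patient coordinates, and every point has a signed distance to a
slice plane along the plane normal.

The mapping follows the DICOM standard: with ``r`` the row index, ``c`` the
column index, ``Δr/Δc`` the between-rows/between-columns spacing and
``u/v`` the unit vectors along increasing column/row index,

    P(r, c) = image_position + c * Δc * u + r * Δr * v

so pixel ``(0, 0)`` maps exactly to ``image_position``.  Fractional indices
are supported throughout (bounding-box centres fall between pixels) and
extrapolation outside the matrix is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .errors import DegenerateBoxError
from .io import DicomSlice

if TYPE_CHECKING:  # pragma: no cover
    from .detection import BoundingBox

#: A patient-space point is a plain length-3 float ndarray (mm, LPS).
PatientPoint = np.ndarray


@dataclass(frozen=True)
class ImagePlane:
    """The oriented plane of a slice: origin, unit normal and in-plane frame."""

    origin: np.ndarray
    normal: np.ndarray
    row_direction: np.ndarray
    column_direction: np.ndarray
    pixel_spacing: tuple[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))
        n = np.asarray(self.normal, dtype=float).reshape(3)
        if abs(np.linalg.norm(n) - 1.0) > 1e-6:
            raise ValueError("plane normal must be a unit vector")
        object.__setattr__(self, "normal", n)


def plane_of_slice(s: DicomSlice) -> ImagePlane:
    """The oriented image plane of a slice."""
    return ImagePlane(
        origin=s.image_position,
        normal=s.normal,
        row_direction=s.row_direction,
        column_direction=s.column_direction,
        pixel_spacing=s.pixel_spacing,
    )


def pixel_to_patient(s: DicomSlice, row, col) -> PatientPoint:
    """Map fractional pixel indices to patient coordinates (mm, LPS).

    ``row`` and ``col`` may be scalars or broadcastable arrays; the result
    has shape ``broadcast(row, col).shape + (3,)`` (a plain 3-vector for
    scalars).
    """
    row = np.asarray(row, dtype=float)
    col = np.asarray(col, dtype=float)
    dr, dc = s.pixel_spacing
    p = (
        s.image_position
        + col[..., None] * dc * s.row_direction
        + row[..., None] * dr * s.column_direction
    )
    return p[()] if p.ndim == 1 else p


def patient_to_pixel(s: DicomSlice, point: PatientPoint):
    """Invert :func:`pixel_to_patient`.

    Returns ``(row, col, out_of_plane)`` where ``out_of_plane`` is the signed
    distance (mm) of ``point`` from the slice plane along the plane normal.
    The inverse is exact (to rounding) for in-plane points.
    """
    d = np.asarray(point, dtype=float) - s.image_position
    dr, dc = s.pixel_spacing
    col = d @ s.row_direction / dc
    row = d @ s.column_direction / dr
    oop = d @ s.normal
    return row, col, oop


def signed_plane_distance(plane: ImagePlane, point: PatientPoint) -> float:
    """Signed distance (mm) from ``point`` to ``plane``.

    Positive on the side the plane normal points toward; linear in the point
    and antisymmetric under a normal flip.
    """
    d = (np.asarray(point, dtype=float) - plane.origin) @ plane.normal
    return float(d) if np.ndim(d) == 0 else d


def bbox_midpoint_patient(s: DicomSlice, box: "BoundingBox") -> PatientPoint:
    """Map a bounding box's centre (mean of min/max indices) to patient space.

    Raises :class:`DegenerateBoxError` when the box has zero extent on
    either axis.
    """
    if box.row_min >= box.row_max or box.col_min >= box.col_max:
        raise DegenerateBoxError(f"degenerate bounding box {box!r}")
    row = 0.5 * (box.row_min + box.row_max)
    col = 0.5 * (box.col_min + box.col_max)
    return pixel_to_patient(s, row, col)
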