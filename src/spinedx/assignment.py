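"""Assigning axial slices to intervertebral-disk levels by directed distances.

Given the six vertebral-body midpoints (L1...S1) in patient space, each
axial slice plane gets six signed distances.  A slice cutting through the
L3-L4 disk lies below the L1, L2, L3 midpoints and above L4, L5, S1, so the
signed distances change sign exactly once, between positions 3 and 4.  That
sign change is the decision rule; a nearest-gap-centre fallback keeps the
assignment total for slices outside the lumbar span or grazing a midpoint.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import AssignmentWarning
from .geometry import plane_of_slice
from .io import DicomSlice, SeriesSet

logger = logging.getLogger("spinedx")

VERTEBRA_LABELS = ("L1", "L2", "L3", "L4", "L5", "S1")


class DiskLevel(enum.Enum):
    """The five lumbar intervertebral-disk levels, superior to inferior."""

    L1_L2 = "L1-L2"
    L2_L3 = "L2-L3"
    L3_L4 = "L3-L4"
    L4_L5 = "L4-L5"
    L5_S1 = "L5-S1"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def from_string(cls, text: str) -> "DiskLevel":
        for level in cls:
            if level.value == text:
                return level
        raise ValueError(f"unknown disk level {text!r}")


DISK_LEVELS: tuple[DiskLevel, ...] = tuple(DiskLevel)


@dataclass(frozen=True)
class VertebraSet:
    """The six labeled vertebral-body midpoints, L1 first (most superior)."""

    midpoints: np.ndarray  # (6, 3) mm, LPS; row order L1..S1

    def __post_init__(self) -> None:
        m = np.asarray(self.midpoints, dtype=float)
        if m.shape != (6, 3):
            raise ValueError("midpoints must have shape (6, 3): L1..S1")
        if not np.all(np.isfinite(m)):
            raise ValueError("midpoints must be finite")
        z = m[:, 2]
        if not np.all(np.diff(z) < 0):
            raise ValueError("midpoint z must strictly decrease from L1 to S1")
        object.__setattr__(self, "midpoints", m)

    def midpoint(self, label: str) -> np.ndarray:
        return self.midpoints[VERTEBRA_LABELS.index(label)]

    @classmethod
    def from_mapping(cls, mapping) -> "VertebraSet":
        return cls(np.stack([np.asarray(mapping[l], dtype=float) for l in VERTEBRA_LABELS]))


@dataclass(frozen=True)
class SliceAssignment:
    """One axial slice's six directed distances and assigned disk level."""

    slice_ref: int  # instance_number
    distances: np.ndarray  # (6,) signed mm, order L1..S1
    level: DiskLevel
    gap_center: float  # signed distance of the assigned gap centre from the plane
    fallback: bool  # True when the sign-change branch did not fire

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float).reshape(6)
        if not np.all(np.isfinite(d)):
            raise ValueError("distances must be finite")
        object.__setattr__(self, "distances", d)


def directed_distances(vertebrae: VertebraSet, axial_slice: DicomSlice) -> np.ndarray:
    """Signed distances (mm) of the six midpoints from the axial slice plane.

    Order L1..S1; positive on the side the plane normal points toward.
    """
    plane = plane_of_slice(axial_slice)
    return (vertebrae.midpoints - plane.origin) @ plane.normal


def _assign(distances: np.ndarray, plausibility_threshold_mm: float):
    d = np.asarray(distances, dtype=float).reshape(6)
    gap_centers = 0.5 * (d[:-1] + d[1:])
    strict = np.flatnonzero(d[:-1] * d[1:] < 0)
    if strict.size == 1:
        idx = int(strict[0])
        fallback = False
    else:
        # No (or ambiguous) strict sign change: nearest gap centre wins,
        # ties to the more superior level (argmin keeps first occurrence).
        idx = int(np.argmin(np.abs(gap_centers)))
        fallback = True
        warnings.warn(
            f"no unique sign change in directed distances {np.round(d, 3)}; "
            f"fell back to nearest gap centre ({DISK_LEVELS[idx].value})",
            AssignmentWarning,
            stacklevel=3,
        )
    gc = float(gap_centers[idx])
    if abs(gc) > plausibility_threshold_mm:
        warnings.warn(
            f"assigned gap centre is {gc:.1f} mm from the slice plane "
            f"(> {plausibility_threshold_mm:g} mm); assignment implausible",
            AssignmentWarning,
            stacklevel=3,
        )
    return idx, fallback, gc


def assign_disk(distances, plausibility_threshold_mm: float = 30.0) -> DiskLevel:
    """Assign a disk level from six signed distances (order L1..S1).

    If exactly one adjacent pair has strictly opposite signs, the slice
    plane passes between those two midpoints and the disk between them is
    returned.  Otherwise the level whose midpoint-pair gap centre is nearest
    the plane is chosen (ties to the more superior level) and an
    :class:`AssignmentWarning` is emitted; a second warning flags gap-centre
    distances beyond ``plausibility_threshold_mm``.
    """
    idx, _, _ = _assign(np.asarray(distances, dtype=float), plausibility_threshold_mm)
    return DISK_LEVELS[idx]


def group_axial_slices(
    series: SeriesSet,
    vertebrae: VertebraSet,
    plausibility_threshold_mm: float = 30.0,
) -> dict[DiskLevel, list[SliceAssignment]]:
    """Assign every axial slice of a series to a disk level.

    Returns a map containing only levels that received at least one slice;
    within a level, slices are ordered superior to inferior (by the signed
    distance of the assigned gap centre, orientation-corrected so the order
    does not depend on which way the slice normals point).
    """
    grouped: dict[DiskLevel, list[tuple[float, SliceAssignment]]] = {}
    for s in series.axial_slices:
        d = directed_distances(vertebrae, s)
        idx, fallback, gc = _assign(d, plausibility_threshold_mm)
        # if the normal points inferior, gap-centre signs flip; re-orient
        # using the superior (z) component so sorting is stable either way
        nz = float(s.normal[2])
        sort_key = gc * (1.0 if nz >= 0 else -1.0)
        assignment = SliceAssignment(
            slice_ref=s.instance_number, distances=d,
            level=DISK_LEVELS[idx], gap_center=gc, fallback=fallback,
        )
        grouped.setdefault(DISK_LEVELS[idx], []).append((sort_key, assignment))

    result: dict[DiskLevel, list[SliceAssignment]] = {}
    for level in DISK_LEVELS:
        if level in grouped:
            pairs = sorted(grouped[level], key=lambda p: p[0])
            result[level] = [a for _, a in pairs]
    logger.info(
        "axial slice counts per level: %s",
        {lvl.value: len(lst) for lvl, lst in result.items()},
    )
    return result
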