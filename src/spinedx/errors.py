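"""Exception and warning hierarchy for spinedx.

All library errors derive from :class:`SpinedxError` so callers (and the
CLI) can distinguish data problems from programming errors.
"""

from __future__ import annotations


class SpinedxError(Exception):
    """Base class for all spinedx errors."""


class MissingTagError(SpinedxError):
    """A DICOM file lacks one of the mandatory geometry tags."""

    def __init__(self, path: str, tag: str) -> None:
        self.path = str(path)
        self.tag = tag
        super().__init__(f"DICOM file {self.path!r} is missing mandatory tag {tag!r}")


class EmptySeriesError(SpinedxError):
    """A directory yielded no slices for a required orientation."""


class DegenerateBoxError(SpinedxError):
    """A bounding box collapses to zero extent on at least one axis."""


class DetectionCountError(SpinedxError):
    """Fewer vertebral-body candidates survived suppression than required."""


class NoDetectionError(SpinedxError):
    """The detector produced no box above the score threshold."""


class ZeroCountError(SpinedxError):
    """A class count of zero makes inverse-frequency weighting undefined."""


class InsufficientSubjectsError(SpinedxError):
    """Too few distinct subjects per class to form grouped CV folds."""


class NotFittedError(SpinedxError):
    """predict_proba was called on a classifier that has not been fit."""


class InvalidSpecError(SpinedxError):
    """A phantom specification violates its own invariants."""


class PipelineStageError(SpinedxError):
    """An error raised by a named pipeline stage, optionally tied to a slice."""

    def __init__(self, stage: str, message: str, slice_ref: int | None = None) -> None:
        self.stage = stage
        self.slice_ref = slice_ref
        where = f"stage {stage!r}"
        if slice_ref is not None:
            where += f", slice {slice_ref}"
        super().__init__(f"{where}: {message}")


class AssignmentWarning(UserWarning):
    """Disk-level assignment fell back to nearest gap center or looks implausible."""


class FeatureExtractionWarning(UserWarning):
    """Shape features could not be extracted from an ROI (empty mask)."""
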