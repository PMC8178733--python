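"""3-class disk classification: normal, bulge, herniation.

The clinical-scale backend (a deep residual network) is modeled as a
pluggable :class:`ClassifierContract`.  The shipped reference backend is a
deterministic shape classifier: it thresholds the ROI, extracts a handful
of morphological features of the disk mask (posterior protrusion depth,
eccentricity, solidity, posterior lobe narrowness, boundary-curvature
extremum) and fits a multinomial logistic model with class weights applied
as observation weights.  Class imbalance is handled by inverse-frequency
cost weighting of the cross-entropy loss, and evaluation uses grouped,
stratified fourfold cross-validation split by subject so no subject's
images leak across folds.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Protocol, Sequence, runtime_checkable

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label as cc_label, regionprops
from skimage.transform import resize
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupKFold, StratifiedGroupKFold

from .assignment import DISK_LEVELS, DiskLevel
from .detection import BoundingBox
from .errors import (
    FeatureExtractionWarning,
    InsufficientSubjectsError,
    NotFittedError,
    ZeroCountError,
)


class ClassLabel(enum.Enum):
    """The three disk conditions."""

    NORMAL = "normal"
    BULGE = "bulge"
    HERNIATION = "herniation"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def from_string(cls, text: str) -> "ClassLabel":
        for c in cls:
            if c.value == text:
                return c
        raise ValueError(f"unknown class label {text!r}")


CLASS_ORDER: tuple[ClassLabel, ...] = (
    ClassLabel.NORMAL,
    ClassLabel.BULGE,
    ClassLabel.HERNIATION,
)

#: Axial image counts per disk level (normal, bulge, herniation) in a
#: 500-patient clinical lumbar MR cohort; used as the default class priors
#: of the phantom generator and for imbalance-weighting examples.
CLINICAL_CLASS_COUNTS: Mapping[DiskLevel, tuple[int, int, int]] = {
    DiskLevel.L1_L2: (593, 37, 36),
    DiskLevel.L2_L3: (549, 120, 30),
    DiskLevel.L3_L4: (347, 284, 86),
    DiskLevel.L4_L5: (158, 413, 178),
    DiskLevel.L5_S1: (238, 242, 244),
}


def aggregate_class_counts(
    counts: Mapping[DiskLevel, tuple[int, int, int]] = CLINICAL_CLASS_COUNTS,
) -> tuple[int, int, int]:
    """Sum per-level class counts over all disk levels."""
    totals = np.sum([counts[lvl] for lvl in counts], axis=0)
    return tuple(int(t) for t in totals)  # type: ignore[return-value]


@dataclass
class RoiImage:
    """A cropped axial disk region, optionally carrying its truth label."""

    pixels: np.ndarray
    level: DiskLevel | None
    truth_label: ClassLabel | None = None
    subject_id: str = ""
    box: BoundingBox | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 2 or p.size == 0:
            raise ValueError("ROI pixels must form a non-empty 2-D grid")
        self.pixels = p


@runtime_checkable
class ClassifierContract(Protocol):
    """Backend contract: fit on labeled ROIs, emit 3-class probabilities."""

    def fit(self, rois: Sequence[RoiImage], class_weights: np.ndarray, seed: int) -> None: ...

    def predict_proba(self, roi: RoiImage) -> np.ndarray: ...


# ---------------------------------------------------------------------------
# cost-sensitive loss


def class_weights_from_counts(counts: Sequence[int]) -> np.ndarray:
    """Inverse-frequency class weights ``w_k = N / (K * n_k)``.

    Balanced counts give all weights 1; rarer classes get proportionally
    larger weights, so a cross-entropy weighted this way prices errors on
    the minority class higher.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (3,):
        raise ValueError("expected exactly three class counts")
    for k, n in enumerate(counts):
        if n <= 0:
            raise ZeroCountError(f"class {CLASS_ORDER[k].value!r} has zero count")
    return counts.sum() / (counts.size * counts)


def cost_sensitive_loss(
    probabilities: Sequence[float], truth: ClassLabel, weights: Sequence[float]
) -> float:
    """Class-weighted cross-entropy ``-w_truth * log p_truth`` (p floored at 1e-12).

    With uniform weights this reduces exactly to the standard cross-entropy.
    """
    p = np.asarray(probabilities, dtype=float)
    w = np.asarray(weights, dtype=float)
    k = CLASS_ORDER.index(truth)
    return float(-w[k] * np.log(max(p[k], 1e-12)))


# ---------------------------------------------------------------------------
# metrics


def confusion_matrix3(
    truths: Sequence[ClassLabel], predictions: Sequence[ClassLabel]
) -> np.ndarray:
    """3x3 confusion matrix; rows = truth, columns = predicted."""
    m = np.zeros((3, 3), dtype=int)
    for t, p in zip(truths, predictions, strict=True):
        m[CLASS_ORDER.index(t), CLASS_ORDER.index(p)] += 1
    return m


def evaluate_metrics(confusion: np.ndarray) -> dict:
    """Accuracy plus one-vs-rest sensitivity and specificity per class.

    A class with zero truth (or zero negative) count reports ``nan`` rather
    than 0 for the undefined rate.
    """
    m = np.asarray(confusion, dtype=float)
    if m.shape != (3, 3) or m.sum() <= 0:
        raise ValueError("confusion matrix must be 3x3 with positive total")
    total = m.sum()
    accuracy = float(np.trace(m) / total)
    sensitivity: dict[ClassLabel, float] = {}
    specificity: dict[ClassLabel, float] = {}
    for k, cls in enumerate(CLASS_ORDER):
        tp = m[k, k]
        fn = m[k].sum() - tp
        fp = m[:, k].sum() - tp
        tn = total - tp - fn - fp
        sensitivity[cls] = float(tp / (tp + fn)) if tp + fn > 0 else float("nan")
        specificity[cls] = float(tn / (tn + fp)) if tn + fp > 0 else float("nan")
    return {"accuracy": accuracy, "sensitivity": sensitivity, "specificity": specificity}


# ---------------------------------------------------------------------------
# reference shape classifier

N_FEATURES = 8


def _pad_resize(pixels: np.ndarray, side: int) -> np.ndarray:
    """Aspect-preserving zero-pad to square, then resample to side x side."""
    h, w = pixels.shape
    size = max(h, w)
    canvas = np.zeros((size, size), dtype=float)
    r0 = (size - h) // 2
    c0 = (size - w) // 2
    canvas[r0:r0 + h, c0:c0 + w] = pixels
    if size == side:
        return canvas
    return resize(canvas, (side, side), order=1, anti_aliasing=True, preserve_range=True)


def _largest_mask(image: np.ndarray) -> np.ndarray | None:
    if np.ptp(image) == 0:
        return None
    mask = image > threshold_otsu(image)
    if not mask.any():
        return None
    labels = cc_label(mask)
    regions = regionprops(labels)
    biggest = max(regions, key=lambda r: r.area)
    return labels == biggest.label


def _max_boundary_curvature(mask: np.ndarray) -> float:
    """Curvature extremum of the (smoothed) outer boundary of the mask."""
    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        return 0.0
    contour = max(contours, key=len)
    if len(contour) < 15:
        return 0.0
    kernel = np.ones(7) / 7.0
    sm = np.column_stack(
        [np.convolve(contour[:, i], kernel, mode="same") for i in (0, 1)]
    )
    d = np.gradient(sm, axis=0)
    dd = np.gradient(d, axis=0)
    num = np.abs(d[:, 0] * dd[:, 1] - d[:, 1] * dd[:, 0])
    den = (d[:, 0] ** 2 + d[:, 1] ** 2) ** 1.5 + 1e-12
    curv = num / den
    inner = curv[7:-7]  # convolution edge effects
    return float(inner.max()) if inner.size else 0.0


def shape_features(pixels: np.ndarray, side: int = 128) -> np.ndarray | None:
    """Morphological features of the disk mask in an ROI, or None if empty.

    Features (posterior = increasing row, the axial rendering convention):

    0. posterior-margin prominence: mean posterior boundary row over the
       central lateral band minus the same over the flanking bands,
       normalized by mask height — negative for a centrally concave margin
       (normal), moderately positive for a broad convex expansion (bulge),
       strongly positive for a focal lobe (herniation)
    1. posterior lobe narrowness: maximum mask width within the
       posterior-most quarter relative to the overall maximum width
       (small for a focal lobe)
    2. row-distribution skewness of the mask (posterior-heavy shapes > 0)
    3. eccentricity of the mask
    4. solidity of the mask (concavities and lobe notches reduce it)
    5. area-normalized posterior protrusion depth,
       ``(row_max - centroid_row) / sqrt(area)``
    6. log1p of the boundary-curvature extremum (scaled by sqrt(area))
    7. moment-based axis ratio, minor/major axis length (size-invariant)
    """
    img = _pad_resize(np.asarray(pixels, dtype=float), side)
    mask = _largest_mask(img)
    if mask is None:
        return None
    region = regionprops(mask.astype(int))[0]
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r_min, r_max = int(rows[0]), int(rows[-1])
    height = r_max - r_min + 1
    area = float(region.area)
    cr = region.centroid[0]

    # posterior boundary profile: last occupied row per occupied column
    rpost = np.array([np.flatnonzero(mask[:, c])[-1] for c in cols], dtype=float)
    w = len(cols)
    cen = w // 2
    central = rpost[max(cen - w // 8, 0): cen + w // 8 + 1]
    flank = np.concatenate(
        [rpost[max(cen - 3 * w // 8, 0): cen - w // 8],
         rpost[cen + w // 8 + 1: cen + 3 * w // 8 + 1]]
    )
    prominence = (
        float(central.mean() - flank.mean()) / height if flank.size and central.size else 0.0
    )

    widths = mask.sum(axis=1)
    q = r_min + 0.75 * (r_max - r_min)
    tail = widths[int(np.ceil(q)): r_max + 1]
    narrowness = float(tail.max() / widths.max()) if tail.size and widths.max() else 0.0

    r_all = np.argwhere(mask)[:, 0].astype(float)
    sd = r_all.std()
    skewness = float(((r_all - r_all.mean()) ** 3).mean() / sd**3) if sd > 0 else 0.0

    protrusion = (r_max - cr) / np.sqrt(area)
    curvature = _max_boundary_curvature(mask) * np.sqrt(area)
    major = region.axis_major_length
    axis_ratio = region.axis_minor_length / major if major > 0 else 1.0
    return np.array(
        [prominence, narrowness, skewness, region.eccentricity, region.solidity,
         protrusion, np.log1p(curvature), axis_ratio]
    )


class ReferenceShapeClassifier:
    """Deterministic shape-feature classifier satisfying the backend contract.

    A multinomial logistic model over :func:`shape_features`, with the class
    weights applied as observation weights during the fit.  Features are
    standardized by the pooled *within-class* standard deviation (global
    scaling would let a class with large spread on one feature — e.g. the
    wide eccentricity range of herniated disks — drown out the same
    feature's fine discrimination between the other two classes).  Given a
    seed it is fully deterministic; ROIs whose mask is empty predict
    uniform probabilities with a :class:`FeatureExtractionWarning`.
    """

    def __init__(self, side: int = 128, C: float = 10.0) -> None:
        self.side = side
        self.C = C
        self._center: np.ndarray | None = None
        self._scale: np.ndarray | None = None
        self._model: LogisticRegression | None = None

    def fit(self, rois: Sequence[RoiImage], class_weights: np.ndarray, seed: int) -> None:
        feats, ys, ws = [], [], []
        class_weights = np.asarray(class_weights, dtype=float)
        for roi in rois:
            if roi.truth_label is None:
                raise ValueError("fit requires labeled ROIs")
            f = shape_features(roi.pixels, self.side)
            if f is None:
                warnings.warn(
                    f"empty mask in training ROI (subject {roi.subject_id!r}); skipped",
                    FeatureExtractionWarning,
                    stacklevel=2,
                )
                continue
            k = CLASS_ORDER.index(roi.truth_label)
            feats.append(f)
            ys.append(k)
            ws.append(class_weights[k])
        X = np.stack(feats)
        y = np.array(ys)
        self._center = X.mean(axis=0)
        present = np.unique(y)
        within_var = np.mean([X[y == k].var(axis=0) for k in present], axis=0)
        self._scale = np.sqrt(within_var) + 1e-9
        self._model = LogisticRegression(
            C=self.C, max_iter=5000, random_state=seed
        )
        self._model.fit((X - self._center) / self._scale, y, sample_weight=np.array(ws))

    def predict_proba(self, roi: RoiImage) -> np.ndarray:
        if self._model is None or self._center is None:
            raise NotFittedError("classifier queried before fit")
        f = shape_features(roi.pixels, self.side)
        if f is None:
            warnings.warn(
                f"empty mask in ROI (subject {roi.subject_id!r}); uniform probabilities",
                FeatureExtractionWarning,
                stacklevel=2,
            )
            return np.full(3, 1.0 / 3.0)
        z = (f[None, :] - self._center) / self._scale
        p = self._model.predict_proba(z)[0]
        out = np.zeros(3)
        for cls_index, p_k in zip(self._model.classes_, p):
            out[int(cls_index)] = p_k
        return out / out.sum()


def reference_shape_classifier(side: int = 128, C: float = 10.0) -> ReferenceShapeClassifier:
    """Factory for the reference backend (default configuration)."""
    return ReferenceShapeClassifier(side=side, C=C)


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVResult:
    """Per-level outcome of grouped fourfold cross-validation."""

    accuracy: float
    confusion: np.ndarray  # (3, 3) ints, rows=truth, cols=predicted
    n_images: int
    metrics: dict = field(default_factory=dict)


def _check_group_counts(rois: Sequence[RoiImage], n_splits: int, level: DiskLevel) -> None:
    per_class: dict[ClassLabel, set[str]] = {c: set() for c in CLASS_ORDER}
    for r in rois:
        assert r.truth_label is not None
        per_class[r.truth_label].add(r.subject_id)
    for cls, subjects in per_class.items():
        if 0 < len(subjects) < n_splits:
            raise InsufficientSubjectsError(
                f"level {level.value}: class {cls.value!r} has only "
                f"{len(subjects)} subject(s); need >= {n_splits} for grouped CV"
            )


def fourfold_cv(
    dataset: Sequence[RoiImage],
    classifier_factory: Callable[[], ClassifierContract],
    seed: int,
    n_splits: int = 4,
) -> dict[DiskLevel, CVResult]:
    """Grouped, stratified fourfold cross-validation per disk level.

    Folds are split by ``subject_id`` (no subject appears in two folds) and
    stratified by class where feasible.  For each level and each fold the
    classifier is fit on the other folds with inverse-frequency class
    weights and evaluated on the held-out fold; confusion matrices are
    summed across folds.  Fully reproducible for a fixed seed.
    """
    results: dict[DiskLevel, CVResult] = {}
    for level in DISK_LEVELS:
        rois = [r for r in dataset if r.level == level]
        if not rois:
            continue
        if any(r.truth_label is None for r in rois):
            raise ValueError(f"level {level.value}: all ROIs must carry truth labels")
        _check_group_counts(rois, n_splits, level)
        y = np.array([CLASS_ORDER.index(r.truth_label) for r in rois])
        groups = np.array([r.subject_id for r in rois])
        counts = np.bincount(y, minlength=3)
        weights = class_weights_from_counts(counts)
        try:
            splitter = StratifiedGroupKFold(n_splits=n_splits, shuffle=True, random_state=seed)
            folds = list(splitter.split(np.zeros(len(rois)), y, groups))
        except ValueError:
            splitter = GroupKFold(n_splits=n_splits)
            folds = list(splitter.split(np.zeros(len(rois)), y, groups))
        confusion = np.zeros((3, 3), dtype=int)
        for train_idx, test_idx in folds:
            clf = classifier_factory()
            clf.fit([rois[i] for i in train_idx], weights, seed)
            for i in test_idx:
                p = clf.predict_proba(rois[i])
                confusion[y[i], int(np.argmax(p))] += 1
        acc = float(np.trace(confusion) / confusion.sum())
        results[level] = CVResult(
            accuracy=acc,
            confusion=confusion,
            n_images=len(rois),
            metrics=evaluate_metrics(confusion),
        )
    return results
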