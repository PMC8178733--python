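"""Cost-sensitive loss, metrics, grouped CV, and the reference shape classifier."""

import numpy as np
import pytest

from spinedx import (
    CLASS_ORDER,
    ClassLabel,
    DiskLevel,
    RoiImage,
    class_weights_from_counts,
    cost_sensitive_loss,
    evaluate_metrics,
    fourfold_cv,
    generate_roi_dataset,
    reference_shape_classifier,
)
from spinedx.classify import aggregate_class_counts
from spinedx.errors import InsufficientSubjectsError, NotFittedError, ZeroCountError


class TestClassWeights:
    def test_balanced_counts_give_unit_weights(self):
        np.testing.assert_allclose(class_weights_from_counts((100, 100, 100)), 1.0)

    def test_hand_example(self):
        np.testing.assert_allclose(
            class_weights_from_counts((1, 1, 2)), (4 / 3, 4 / 3, 2 / 3)
        )

    def test_cohort_counts_weight_ratio(self):
        n_normal, n_bulge, n_hern = aggregate_class_counts()
        w = class_weights_from_counts((n_normal, n_bulge, n_hern))
        np.testing.assert_allclose(
            w, (3555 / (3 * 1885), 3555 / (3 * 1096), 3555 / (3 * 574))
        )
        assert w[2] / w[0] == pytest.approx(1885 / 574, abs=1e-9)

    def test_zero_count_rejected(self):
        with pytest.raises(ZeroCountError, match="bulge"):
            class_weights_from_counts((10, 0, 5))


class TestCostSensitiveLoss:
    def test_perfect_prediction_is_zero(self):
        assert cost_sensitive_loss((0, 1, 0), ClassLabel.BULGE, (5, 5, 5)) == 0.0

    def test_uniform_probability_closed_form(self):
        p = (1 / 3, 1 / 3, 1 / 3)
        assert cost_sensitive_loss(p, ClassLabel.NORMAL, (1, 1, 1)) == pytest.approx(
            np.log(3)
        )

    def test_linear_in_truth_weight(self):
        p = (0.2, 0.5, 0.3)
        base = cost_sensitive_loss(p, ClassLabel.HERNIATION, (1, 1, 1))
        assert cost_sensitive_loss(p, ClassLabel.HERNIATION, (1, 1, 2)) == pytest.approx(
            2 * base
        )

    def test_uniform_weights_reduce_to_cross_entropy(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.dirichlet(np.ones(3))
            truth = CLASS_ORDER[rng.integers(3)]
            expected = -np.log(max(p[CLASS_ORDER.index(truth)], 1e-12))
            assert cost_sensitive_loss(p, truth, np.ones(3)) == pytest.approx(
                expected, abs=1e-12
            )


class TestEvaluateMetrics:
    def test_perfect_diagonal(self):
        m = evaluate_metrics(np.diag([10, 10, 10]))
        assert m["accuracy"] == 1.0
        assert all(v == 1.0 for v in m["sensitivity"].values())
        assert all(v == 1.0 for v in m["specificity"].values())

    def test_hand_example_one_vs_rest(self):
        m = evaluate_metrics(np.array([[8, 2, 0], [1, 9, 0], [0, 0, 10]]))
        assert m["accuracy"] == pytest.approx(27 / 30)
        assert m["sensitivity"][ClassLabel.NORMAL] == pytest.approx(0.8)
        assert m["specificity"][ClassLabel.NORMAL] == pytest.approx(19 / 20)

    def test_single_predicted_column(self):
        m = evaluate_metrics(np.array([[5, 0, 0], [7, 0, 0], [3, 0, 0]]))
        assert m["sensitivity"][ClassLabel.NORMAL] == 1.0
        assert m["sensitivity"][ClassLabel.BULGE] == 0.0

    def test_zero_truth_class_reports_nan(self):
        m = evaluate_metrics(np.array([[5, 1, 0], [2, 6, 0], [0, 0, 0]]))
        assert np.isnan(m["sensitivity"][ClassLabel.HERNIATION])

    def test_accuracy_is_count_weighted_mean_sensitivity(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            c = rng.integers(1, 40, size=(3, 3))
            m = evaluate_metrics(c)
            row_tot = c.sum(axis=1)
            sens = np.array([m["sensitivity"][cls] for cls in CLASS_ORDER])
            assert m["accuracy"] == pytest.approx((sens * row_tot).sum() / c.sum())


@pytest.fixture(scope="module")
def small_roi_dataset():
    # 24 subjects/level -> 8 per class with balanced cycling
    return generate_roi_dataset(n_per_level=24, seed=21)


class TestFourfoldCV:
    def test_deterministic_for_fixed_seed(self, small_roi_dataset):
        r1 = fourfold_cv(small_roi_dataset, reference_shape_classifier, seed=5)
        r2 = fourfold_cv(small_roi_dataset, reference_shape_classifier, seed=5)
        for lvl in r1:
            np.testing.assert_array_equal(r1[lvl].confusion, r2[lvl].confusion)

    def test_no_subject_spans_two_folds(self, small_roi_dataset):
        """Grouped splitting assigns each subject to exactly one test fold."""
        from sklearn.model_selection import StratifiedGroupKFold

        rois = [r for r in small_roi_dataset if r.level == DiskLevel.L3_L4]
        y = np.array([CLASS_ORDER.index(r.truth_label) for r in rois])
        groups = np.array([r.subject_id for r in rois])
        seen = {}
        splitter = StratifiedGroupKFold(n_splits=4, shuffle=True, random_state=5)
        for fold, (_, test_idx) in enumerate(
            splitter.split(np.zeros(len(rois)), y, groups)
        ):
            for i in test_idx:
                assert seen.setdefault(groups[i], fold) == fold

    def test_insufficient_subjects_rejected(self):
        rois = generate_roi_dataset(n_per_level=6, seed=3)  # 2 subjects per class
        with pytest.raises(InsufficientSubjectsError):
            fourfold_cv(rois, reference_shape_classifier, seed=1)


class TestReferenceShapeClassifier:
    def test_predict_before_fit_rejected(self, small_roi_dataset):
        clf = reference_shape_classifier()
        with pytest.raises(NotFittedError):
            clf.predict_proba(small_roi_dataset[0])

    def test_probabilities_sum_to_one(self, small_roi_dataset):
        clf = reference_shape_classifier()
        clf.fit(small_roi_dataset, np.ones(3), seed=0)
        p = clf.predict_proba(small_roi_dataset[0])
        assert p.sum() == pytest.approx(1.0, abs=1e-9) and (p >= 0).all()

    def test_ellipses_classified_normal(self, small_roi_dataset):
        clf = reference_shape_classifier()
        clf.fit(small_roi_dataset, np.ones(3), seed=0)
        probe = generate_roi_dataset(n_per_level=4, seed=77)
        ellipses = [r for r in probe if r.truth_label is ClassLabel.NORMAL]
        preds = [CLASS_ORDER[int(np.argmax(clf.predict_proba(r)))] for r in ellipses]
        assert all(p is ClassLabel.NORMAL for p in preds)

    def test_focal_lobe_recall(self, small_roi_dataset):
        clf = reference_shape_classifier()
        clf.fit(small_roi_dataset, np.ones(3), seed=0)
        probe = generate_roi_dataset(n_per_level=8, seed=78)
        lobes = [r for r in probe if r.truth_label is ClassLabel.HERNIATION]
        hits = sum(
            CLASS_ORDER[int(np.argmax(clf.predict_proba(r)))] is ClassLabel.HERNIATION
            for r in lobes
        )
        assert hits / len(lobes) >= 0.9

    def test_empty_mask_predicts_uniform_with_warning(self, small_roi_dataset):
        from spinedx.errors import FeatureExtractionWarning

        clf = reference_shape_classifier()
        clf.fit(small_roi_dataset, np.ones(3), seed=0)
        blank = RoiImage(pixels=np.zeros((32, 32)), level=DiskLevel.L1_L2)
        with pytest.warns(FeatureExtractionWarning):
            p = clf.predict_proba(blank)
        np.testing.assert_allclose(p, 1 / 3)
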