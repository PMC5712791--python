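"""Detection metrics: confusion counts, rates, ROC/AUC, relative error."""

import numpy as np
import pytest

from dropcount.evaluation import (
    ConfusionCounts,
    object_confusion,
    pixel_confusion,
    rates_and_f,
    relative_error,
    roc_curve,
)
from dropcount.types import Circle, CircleSet


class TestPixelConfusion:
    def test_identical_maps_all_true_positive(self, rng):
        truth = rng.random((20, 20)) > 0.6
        c = pixel_confusion(truth, truth)
        assert (c.tp, c.fp, c.fn) == (truth.sum(), 0, 0)
        assert c.n_targets == truth.sum()

    def test_all_false_detection(self, rng):
        truth = rng.random((20, 20)) > 0.6
        c = pixel_confusion(np.zeros_like(truth), truth)
        assert c.tp == 0 and c.fn == truth.sum()

    def test_matches_elementwise_tally(self, rng):
        det = rng.random((15, 17)) > 0.5
        truth = rng.random((15, 17)) > 0.5
        c = pixel_confusion(det, truth)
        tp = fp = fn = 0
        for i in range(15):
            for j in range(17):
                if det[i, j] and truth[i, j]:
                    tp += 1
                elif det[i, j]:
                    fp += 1
                elif truth[i, j]:
                    fn += 1
        assert (c.tp, c.fp, c.fn) == (tp, fp, fn)
        assert c.n_background == (~truth).sum()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pixel_confusion(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


class TestObjectConfusion:
    def test_truth_replayed_is_perfect(self):
        truth = CircleSet([Circle(50, 50, 20), Circle(50, 110, 20), Circle(120, 80, 18)])
        c = object_confusion(truth, truth)
        assert (c.tp, c.fp, c.fn) == (3, 0, 0)

    def test_one_detection_between_two_truths(self):
        """Greedy one-to-one matching: a single hit cannot count twice."""
        truth = CircleSet([Circle(50, 40, 20), Circle(50, 80, 20)])
        det = CircleSet([Circle(50, 58, 20)])
        c = object_confusion(det, truth)
        assert (c.tp, c.fp, c.fn) == (1, 0, 1)

    def test_far_detection_is_false_positive(self):
        truth = CircleSet([Circle(50, 50, 20)])
        det = CircleSet([Circle(50, 90, 20)])  # 2r away
        c = object_confusion(det, truth)
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    def test_match_gate_is_truth_radius(self):
        truth = CircleSet([Circle(50, 50, 10)])
        inside = CircleSet([Circle(50, 59, 10)])
        outside = CircleSet([Circle(50, 61, 10)])
        assert object_confusion(inside, truth).tp == 1
        assert object_confusion(outside, truth).tp == 0


class TestRates:
    def test_symmetric_case(self):
        c = ConfusionCounts(tp=95, fp=5, fn=5, n_targets=100, n_background=10_000)
        r = rates_and_f(c)
        assert r.recall == pytest.approx(0.95)
        assert r.precision == pytest.approx(0.95)
        assert r.f_measure == pytest.approx(0.95)
        assert r.fpr == pytest.approx(5 / 10_000)

    def test_perfect_detection(self):
        r = rates_and_f(ConfusionCounts(tp=50, fp=0, fn=0, n_targets=50, n_background=100))
        assert (r.tpr, r.fpr, r.f_measure) == (1.0, 0.0, 1.0)

    def test_harmonic_mean_formula(self):
        c = ConfusionCounts(tp=96, fp=4, fn=5, n_targets=101, n_background=1000)
        r = rates_and_f(c)
        prec, rec = 96 / 100, 96 / 101
        assert r.f_measure == pytest.approx(2 * prec * rec / (prec + rec), abs=1e-12)

    def test_f_bounded_by_weaker_side(self, rng):
        """F <= 2*min(P,R)/(1 + min(P,R)) for any confusion counts."""
        for _ in range(50):
            tp = int(rng.integers(0, 50))
            fp = int(rng.integers(0, 50))
            fn = int(rng.integers(1, 50))
            r = rates_and_f(
                ConfusionCounts(tp=tp, fp=fp, fn=fn, n_targets=tp + fn, n_background=100)
            )
            m = min(r.precision, r.recall)
            assert r.f_measure <= 2 * m / (1 + m) + 1e-12

    def test_zero_targets_rejected(self):
        with pytest.raises(ValueError):
            rates_and_f(ConfusionCounts(tp=0, fp=0, fn=0, n_targets=0, n_background=10))


class TestRoc:
    def test_perfectly_separable_auc_one(self):
        img = np.where(np.arange(100).reshape(10, 10) < 50, 0.2, 0.8)
        truth = img > 0.5
        points, auc = roc_curve(img, truth)
        assert auc == pytest.approx(1.0, abs=1e-9)

    def test_random_truth_chance_level(self):
        aucs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            img = rng.random((60, 60))
            truth = rng.random((60, 60)) > 0.5
            aucs.append(roc_curve(img, truth)[1])
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_minimal_two_threshold_grid(self):
        rng = np.random.default_rng(0)
        img = rng.random((20, 20))
        truth = img > 0.7
        points, auc = roc_curve(img, truth, thresholds=[0.0, 1.0])
        assert 0.0 <= auc <= 1.0
        assert (points[0] == [0.0, 0.0]).all() and (points[-1] == [1.0, 1.0]).all()

    def test_curve_monotone_after_fpr_sort(self, rng):
        img = np.clip(rng.random((50, 50)), 0, 1)
        truth = (img + rng.normal(0, 0.3, img.shape)) > 0.6
        if truth.all() or not truth.any():
            pytest.skip("degenerate draw")
        points, auc = roc_curve(img, truth)
        assert np.all(np.diff(points[:, 1]) >= -1e-12)
        assert 0.0 <= auc <= 1.0

    def test_degenerate_truth_rejected(self):
        with pytest.raises(ValueError):
            roc_curve(np.zeros((5, 5)), np.ones((5, 5), bool))


class TestRelativeError:
    @pytest.mark.parametrize(
        "true,detected,expected",
        [(16, 17, 6.25), (33, 35, 6.06), (100, 100, 0.0)],
    )
    def test_percentage_to_two_decimals(self, true, detected, expected):
        assert relative_error(true, detected) == expected

    def test_zero_true_count_rejected(self):
        with pytest.raises(ValueError):
            relative_error(0, 5)
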