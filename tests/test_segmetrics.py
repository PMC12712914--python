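import numpy as np
import pytest
from scipy.spatial.distance import cdist

from srshisto import segmetrics as sm
from tests.conftest import blobby_labels


def brute_boundary_points(labels, k):
    """Independent O(N^2) boundary extraction by explicit neighbour scan."""
    mask = labels == k
    h, w = labels.shape
    pts = []
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w and not mask[yy, xx]:
                        pts.append((y, x))
                        break
                else:
                    continue
                break
    return np.array(pts, dtype=float)


def brute_bf1(pred, truth, k, tol):
    bp = brute_boundary_points(pred, k)
    bt = brute_boundary_points(truth, k)
    if len(bp) == 0 or len(bt) == 0:
        return None
    d = cdist(bp, bt)
    prec = (d.min(axis=1) <= tol).mean()
    rec = (d.min(axis=0) <= tol).mean()
    return 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)


class TestConfusion:
    def test_perfect_prediction_has_no_errors(self, rng):
        labels = rng.integers(0, 4, (8, 8))
        c = sm.confusion(labels, labels, 4)
        assert not c.fp.any() and not c.fn.any()

    def test_hand_enumerated_two_by_two(self):
        truth = np.array([[0, 0], [1, 1]])
        pred = np.array([[0, 1], [1, 1]])
        c = sm.confusion(pred, truth, 2)
        assert (c.tp[1], c.fp[1], c.fn[1], c.tn[1]) == (2, 1, 0, 1)

    def test_swapping_maps_exchanges_fp_fn(self, rng):
        a = rng.integers(0, 3, (10, 10))
        b = rng.integers(0, 3, (10, 10))
        c1, c2 = sm.confusion(a, b, 3), sm.confusion(b, a, 3)
        np.testing.assert_array_equal(c1.fp, c2.fn)
        np.testing.assert_array_equal(c1.fn, c2.fp)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sm.confusion(np.zeros((2, 2), int), np.zeros((2, 3), int), 2)


class TestClassMetrics:
    def test_perfect_prediction_scores_one(self, rng):
        labels = rng.integers(0, 3, (8, 8))
        rep = sm.class_metrics(sm.confusion(labels, labels, 3))
        for k in np.unique(labels):
            assert rep.iou[k] == rep.dice[k] == rep.precision[k] == 1.0

    def test_hand_computed_counts(self):
        truth = np.array([[0, 0], [1, 1]])
        pred = np.array([[0, 1], [1, 1]])
        rep = sm.class_metrics(sm.confusion(pred, truth, 2))
        assert rep.iou[1] == pytest.approx(2 / 3)
        assert rep.precision[1] == pytest.approx(2 / 3)
        assert rep.recall[1] == 1.0
        assert rep.dice[1] == pytest.approx(0.8)
        assert rep.acc[1] == pytest.approx(0.75)

    def test_disjoint_masks_score_zero(self):
        truth = np.array([[1, 1], [0, 0]])
        pred = np.array([[0, 0], [1, 1]])
        rep = sm.class_metrics(sm.confusion(pred, truth, 2))
        assert rep.iou[1] == rep.dice[1] == 0.0

    def test_dice_iou_identity_on_random_maps(self, rng):
        for _ in range(20):
            pred = rng.integers(0, 4, (12, 12))
            truth = rng.integers(0, 4, (12, 12))
            rep = sm.class_metrics(sm.confusion(pred, truth, 4))
            np.testing.assert_allclose(rep.dice, 2 * rep.iou / (1 + rep.iou))

    def test_confusion_metrics_invariant_to_joint_pixel_permutation(self, rng):
        pred = rng.integers(0, 3, (9, 9))
        truth = rng.integers(0, 3, (9, 9))
        perm = rng.permutation(81)
        rep1 = sm.class_metrics(sm.confusion(pred, truth, 3))
        rep2 = sm.class_metrics(sm.confusion(
            pred.ravel()[perm].reshape(9, 9), truth.ravel()[perm].reshape(9, 9), 3))
        np.testing.assert_array_equal(rep1.iou, rep2.iou)
        np.testing.assert_array_equal(rep1.dice, rep2.dice)

    def test_absent_class_excluded_from_means(self):
        labels = np.ones((4, 4), dtype=int)
        rep = sm.class_metrics(sm.confusion(labels, labels, 3))
        assert not rep.present[2]
        assert rep.miou == 1.0


class TestBoundaryF1:
    def test_identical_maps_score_one(self, rng):
        labels = blobby_labels(32, 32, 3, rng)
        bf1 = sm.boundary_f1(labels, labels, 6, 3)
        for k in np.unique(labels):
            assert bf1[k] == 1.0

    def test_shift_within_tolerance_scores_one(self):
        truth = np.zeros((20, 20), dtype=int)
        truth[5:15, 5:15] = 1
        pred = np.roll(truth, 3, axis=1)
        assert sm.boundary_f1(pred, truth, 6, 2)[1] == 1.0

    def test_shift_beyond_tolerance_penalised(self):
        truth = np.zeros((20, 20), dtype=int)
        truth[5:15, 5:15] = 1
        pred = np.roll(truth, 3, axis=1)
        assert sm.boundary_f1(pred, truth, 1, 2)[1] < 1.0
        # oracle agreement at the strict tolerance
        assert sm.boundary_f1(pred, truth, 1, 2)[1] == pytest.approx(
            brute_bf1(pred, truth, 1, 1.0))

    def test_monotone_in_tolerance(self, rng):
        pred = blobby_labels(32, 32, 3, rng)
        truth = blobby_labels(32, 32, 3, rng)
        prev = np.zeros(3)
        for tol in (0, 1, 2, 4, 8):
            cur = np.nan_to_num(sm.boundary_f1(pred, truth, tol, 3), nan=1.0)
            assert (cur >= prev - 1e-12).all()
            prev = cur

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            h, w = rng.integers(12, 40, 2)
            pred = blobby_labels(h, w, 3, rng)
            truth = blobby_labels(h, w, 3, rng)
            tol = float(rng.integers(1, 7))
            fast = sm.boundary_f1(pred, truth, tol, 3)
            for k in range(3):
                oracle = brute_bf1(pred, truth, k, tol)
                if oracle is not None:
                    assert fast[k] == pytest.approx(oracle)


class TestErrorMap:
    def test_equal_maps_have_no_mismatch(self, rng):
        labels = rng.integers(0, 3, (6, 6))
        em = sm.error_map(labels, labels)
        assert not (em == sm.ERROR_MISMATCH).any()

    def test_single_flipped_pixel(self):
        truth = np.ones((4, 4), dtype=int)
        pred = truth.copy()
        pred[2, 2] = 2
        assert (sm.error_map(pred, truth) == sm.ERROR_MISMATCH).sum() == 1

    def test_counting_identity(self, rng):
        pred = rng.integers(0, 3, (16, 16))
        truth = rng.integers(0, 3, (16, 16))
        em = sm.error_map(pred, truth)
        n = {v: int((em == v).sum()) for v in
             (sm.ERROR_MATCH, sm.ERROR_MISMATCH, sm.ERROR_IGNORED)}
        assert sum(n.values()) == 256

    def test_background_background_ignored(self):
        z = np.zeros((3, 3), dtype=int)
        assert (sm.error_map(z, z) == sm.ERROR_IGNORED).all()
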