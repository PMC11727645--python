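"""Confusion-count metrics and the morphology-aware CAL / LCC suite."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.morphology import skeletonize

from vdmnet import metrics as M

# ---------------------------------------------------------------------------
# brute-force oracles: literal per-pixel evaluation of the set expressions


def brute_dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    """p is in the dilation iff some foreground q lies within the disc."""
    h, w = mask.shape
    offsets = [(dy, dx) for dy in range(-radius, radius + 1)
               for dx in range(-radius, radius + 1)
               if dy * dy + dx * dx <= radius * radius]
    out = np.zeros_like(mask, dtype=bool)
    for i in range(h):
        for j in range(w):
            out[i, j] = any(
                0 <= i + dy < h and 0 <= j + dx < w and mask[i + dy, j + dx]
                for dy, dx in offsets)
    return out


def brute_area(pred, gt, radius=1):
    pred, gt = pred.astype(bool), gt.astype(bool)
    numer = (brute_dilate(pred, radius) & gt) | (pred & brute_dilate(gt, radius))
    return numer.sum() / (pred | gt).sum()


def brute_length(pred, gt, radius=1):
    pred, gt = pred.astype(bool), gt.astype(bool)
    sp, sg = skeletonize(pred), skeletonize(gt)
    numer = (sp & brute_dilate(gt, radius)) | (brute_dilate(pred, radius) & sg)
    return numer.sum() / (sp | sg).sum()


def random_small_mask(rng, shape=(12, 14), density=0.25):
    return (rng.random(shape) < density).astype(np.uint8)


# ---------------------------------------------------------------------------
# confusion-count metrics


class TestConfusionCounts:
    def test_identity(self):
        gt = np.zeros((4, 4), dtype=np.uint8)
        gt[1:3, 1:3] = 1
        c = M.confusion_counts(gt, gt)
        assert (c.tp, c.tn, c.fp, c.fn) == (4, 12, 0, 0)
        assert c.total == 16

    def test_complement(self):
        gt = np.array([[1, 0], [0, 1]], dtype=np.uint8)
        c = M.confusion_counts(1 - gt, gt)
        assert c.tp == 0 and c.tn == 0 and c.fp == 2 and c.fn == 2

    def test_four_pixel_enumeration(self):
        gt = np.array([[1, 1, 0, 0]])
        pred = np.array([[1, 0, 1, 0]])
        c = M.confusion_counts(pred, gt)
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 1)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            M.confusion_counts(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            M.confusion_counts(np.full((2, 2), 3), np.zeros((2, 2)))


class TestOverlapMetrics:
    def test_perfect(self):
        c = M.ConfusionCounts(tp=1, fp=0, fn=0, tn=0)
        assert M.dice(c) == M.jaccard(c) == M.recall(c) == 1.0

    def test_hand_computed_dice_jaccard(self):
        c = M.ConfusionCounts(tp=2, fp=1, fn=1, tn=0)
        assert M.dice(c) == pytest.approx(4 / 6)
        assert M.jaccard(c) == pytest.approx(0.5)

    def test_hand_computed_bacc_recall(self):
        c = M.ConfusionCounts(tp=1, fn=1, tn=2, fp=0)
        assert M.bacc(c) == pytest.approx(0.75)
        assert M.recall(c) == pytest.approx(0.5)

    def test_all_background_agreement_is_perfect(self):
        c = M.ConfusionCounts(tp=0, fp=0, fn=0, tn=9)
        assert M.dice(c) == M.jaccard(c) == M.recall(c) == 1.0

    def test_bacc_single_class(self):
        # no negatives in gt: only the sensitivity half is defined
        c = M.ConfusionCounts(tp=3, fn=1, fp=0, tn=0)
        assert M.bacc(c) == pytest.approx(0.75)

    @given(tp=st.integers(0, 50), fp=st.integers(0, 50), fn=st.integers(0, 50))
    @settings(max_examples=60, deadline=None)
    def test_dice_jaccard_identity(self, tp, fp, fn):
        c = M.ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=5)
        d, j = M.dice(c), M.jaccard(c)
        assert d == pytest.approx(2 * j / (1 + j))

    def test_dice_monotone_under_filling(self):
        # growing pred toward gt never decreases dice
        gt = np.zeros((8, 8), dtype=np.uint8)
        gt[2:6, 2:6] = 1
        pred = np.zeros_like(gt)
        prev = M.dice(M.confusion_counts(pred, gt))
        for i, j in zip(*np.nonzero(gt)):
            pred[i, j] = 1
            cur = M.dice(M.confusion_counts(pred, gt))
            assert cur >= prev
            prev = cur


# ---------------------------------------------------------------------------
# CAL factors


class TestConnectivity:
    def test_identical_masks(self):
        m = np.zeros((6, 6), dtype=np.uint8)
        m[1, 1:4] = 1
        assert M.connectivity_C(m, m) == 1.0

    def test_empty_prediction(self):
        gt = np.zeros((20, 20), dtype=np.uint8)
        gt[1, 0:40 // 2] = 1   # 3 separate strokes, 100 px total
        gt[5, 0:20] = 1
        gt[9:13, 0:15] = 1
        # rebuild exactly: 3 components, 100 pixels
        gt = np.zeros((20, 20), dtype=np.uint8)
        gt[1, 0:20] = 1
        gt[5, 0:20] = 1
        gt[9:12, 0:20] = 1
        assert int(gt.sum()) == 100
        assert M.connectivity_C(np.zeros_like(gt), gt) == pytest.approx(0.97)

    def test_shattered_prediction_clamps_to_zero(self):
        gt = np.zeros((8, 8), dtype=np.uint8)
        gt[0, 0:4] = 1  # 4 px, 1 component
        pred = np.zeros_like(gt)
        # 6 isolated pixels: |1 - 6| > 4 -> clamp
        for k, (i, j) in enumerate([(0, 0), (0, 2), (2, 0), (2, 2), (4, 4), (6, 6)]):
            pred[i, j] = 1
        assert M.connectivity_C(pred, gt) == 0.0

    def test_empty_gt_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            M.connectivity_C(np.ones((4, 4), dtype=np.uint8), np.zeros((4, 4), dtype=np.uint8))


class TestAreaFactor:
    def test_identity(self):
        m = np.zeros((8, 8), dtype=np.uint8)
        m[2:5, 2:7] = 1
        for r in (0, 1, 2):
            assert M.area_A(m, m, r) == 1.0

    def test_far_disjoint_masks(self):
        a = np.zeros((10, 10), dtype=np.uint8)
        b = np.zeros_like(a)
        a[0, 0] = 1
        b[9, 9] = 1
        assert M.area_A(a, b, 1) == 0.0

    def test_parallel_lines_offset_one(self):
        a = np.zeros((5, 8), dtype=np.uint8)
        b = np.zeros_like(a)
        a[2, 1:7] = 1
        b[3, 1:7] = 1
        assert M.area_A(a, b, 1) == 1.0

    def test_matches_bruteforce_on_random_masks(self, rng):
        for _ in range(5):
            pred, gt = random_small_mask(rng), random_small_mask(rng)
            if not (pred | gt).any():
                continue
            for r in (1, 2):
                assert M.area_A(pred, gt, r) == pytest.approx(brute_area(pred, gt, r))


class TestLengthFactor:
    def test_identity(self):
        m = np.zeros((8, 8), dtype=np.uint8)
        m[3, 1:7] = 1
        assert M.length_L(m, m, 1) == 1.0

    def test_far_disjoint(self):
        a = np.zeros((12, 12), dtype=np.uint8)
        b = np.zeros_like(a)
        a[0, 0:4] = 1
        b[11, 8:12] = 1
        assert M.length_L(a, b, 1) == 0.0

    def test_shifted_line_within_tolerance(self):
        a = np.zeros((6, 10), dtype=np.uint8)
        b = np.zeros_like(a)
        a[2, 1:9] = 1
        b[3, 1:9] = 1
        assert M.length_L(a, b, 1) == 1.0

    def test_matches_bruteforce_on_random_masks(self, rng):
        for _ in range(5):
            pred, gt = random_small_mask(rng), random_small_mask(rng)
            if not pred.any() or not gt.any():
                continue
            assert M.length_L(pred, gt, 1) == pytest.approx(brute_length(pred, gt, 1))


class TestCalAndLcc:
    def test_cal_perfect_on_any_nonempty_mask(self, rng):
        for _ in range(3):
            m = random_small_mask(rng, (16, 16))
            if not m.any():
                continue
            assert M.cal(m, m) == pytest.approx(100.0)

    def test_cal_empty_prediction_is_zero(self):
        gt = np.zeros((8, 8), dtype=np.uint8)
        gt[2, 2:6] = 1
        assert M.cal(np.zeros_like(gt), gt) == 0.0

    def test_cal_bounded_by_worst_factor(self, rng):
        pred, gt = random_small_mask(rng), random_small_mask(rng)
        comp = M.cal_components(pred, gt)
        for f in (comp.c, comp.a, comp.l):
            assert 0.0 <= f <= 1.0
        assert comp.cal <= 100.0 * min(comp.c, comp.a, comp.l) + 1e-12

    def test_lcc_identity(self):
        m = np.zeros((10, 10), dtype=np.uint8)
        m[4, 1:9] = 1
        assert M.lcc(m, m) == 100.0

    def test_lcc_hand_computed_ratio(self):
        gt = np.zeros((4, 110), dtype=np.uint8)
        gt[1, 1:101] = 1    # skeleton length 100
        pred = np.zeros_like(gt)
        pred[1, 1:81] = 1   # skeleton length 80
        assert M.lcc(pred, gt) == pytest.approx(80.0)

    def test_lcc_overlong_clamps(self):
        gt = np.zeros((4, 50), dtype=np.uint8)
        gt[1, 1:11] = 1     # length 10
        pred = np.zeros_like(gt)
        pred[1, 1:41] = 1   # length 40 -> |40-10|/10 > 1
        assert M.lcc(pred, gt) == 0.0

    def test_empty_gt_skeleton_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            M.lcc(np.ones((4, 4), dtype=np.uint8), np.zeros((4, 4), dtype=np.uint8))


class TestEvaluate:
    def test_perfect_prediction(self, vessel_sample):
        m = vessel_sample.mask
        s = M.evaluate(m.astype(float), m)
        assert s.dice == s.jac == s.bacc == s.rec == 1.0
        assert s.cal == pytest.approx(100.0)
        assert s.lcc == pytest.approx(100.0)

    def test_inverted_prediction_zero_dice(self, vessel_sample):
        m = vessel_sample.mask
        s = M.evaluate(1.0 - m.astype(float), m)
        assert s.dice == 0.0

    def test_threshold_determinism(self, rng, vessel_sample):
        prob = np.clip(vessel_sample.mask * 0.7 + rng.uniform(0, 0.3, vessel_sample.mask.shape), 0, 1)
        a = M.evaluate(prob, vessel_sample.mask, threshold=0.5)
        b = M.evaluate(prob, vessel_sample.mask, threshold=0.5)
        assert a == b

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            M.evaluate(np.full((4, 4), 1.5), np.zeros((4, 4), dtype=np.uint8))

    def test_geometric_invariance(self, vessel_sample, rng):
        """All six metrics are invariant under joint flips / 90-degree turns."""
        prob = np.clip(vessel_sample.mask * 0.8 + rng.uniform(0, 0.25, vessel_sample.mask.shape), 0, 1)
        gt = vessel_sample.mask
        base = M.evaluate(prob, gt).as_dict()
        for op in (np.fliplr, np.flipud, np.rot90):
            got = M.evaluate(op(prob).copy(), op(gt).copy()).as_dict()
            for key in base:
                assert got[key] == pytest.approx(base[key]), (op.__name__, key)
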