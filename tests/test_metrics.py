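"""Voxel and lesion metric correctness against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csrseg import metrics
from csrseg.grids import LabelVolume

from conftest import make_labels


def brute_confusion(pred, gt):
    """Exhaustive per-voxel loop, the independent oracle."""
    tp = fp = fn = 0
    for idx in np.ndindex(pred.shape):
        p, g = bool(pred[idx]), bool(gt[idx])
        tp += p and g
        fp += p and not g
        fn += (not p) and g
    return tp, fp, fn


class TestConfusion:
    def test_identical_masks(self):
        gt = np.zeros((4, 4, 2), bool)
        gt[1:3, 1:3, :] = True
        c = metrics.confusion(gt, gt)
        assert (c.tp, c.fp, c.fn) == (8, 0, 0)

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 1), bool)
        b = np.zeros((4, 4, 1), bool)
        a[:2] = True
        b[3:] = True
        c = metrics.confusion(a, b)
        assert (c.tp, c.fp, c.fn) == (0, 8, 4)

    def test_matches_bruteforce_on_random_masks(self, rng):
        for _ in range(25):
            p = rng.random((6, 6, 6)) > 0.5
            g = rng.random((6, 6, 6)) > 0.5
            c = metrics.confusion(p, g)
            assert (c.tp, c.fp, c.fn) == brute_confusion(p, g)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            metrics.confusion(np.zeros((2, 2, 2)), np.zeros((3, 2, 2)))


class TestVoxelMetrics:
    def test_hand_computed_counts(self):
        c = metrics.ConfusionCounts(tp=2, fp=1, fn=1)
        assert metrics.dice(c) == pytest.approx(4 / 6)
        assert metrics.iou(c) == pytest.approx(0.5)
        assert metrics.vs(c) == pytest.approx(1.0)

    def test_empty_vs_empty_convention(self):
        c = metrics.ConfusionCounts(0, 0, 0)
        assert metrics.dice(c) == metrics.iou(c) == metrics.vs(c) == 1.0

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_dice_iou_identity(self, tp, fp, fn):
        c = metrics.ConfusionCounts(tp, fp, fn)
        d, j = metrics.dice(c), metrics.iou(c)
        assert 0 <= j <= d <= 1
        assert d == pytest.approx(2 * j / (1 + j), abs=1e-12)

    def test_adding_true_positive_never_decreases_dice(self, rng):
        for _ in range(20):
            tp, fp, fn = (int(v) for v in rng.integers(0, 20, 3))
            d0 = metrics.dice(metrics.ConfusionCounts(tp, fp, fn))
            d1 = metrics.dice(metrics.ConfusionCounts(tp + 1, fp, fn))
            assert d1 >= d0 - 1e-15


class TestLongDiameter:
    def test_two_voxel_pair_at_mri_spacing(self):
        mask = np.zeros((20, 4, 2), bool)
        mask[2, 1, 0] = mask[18, 1, 0] = True
        d = metrics.long_diameter(mask, (0.5938, 1.0, 5.0))
        assert d == pytest.approx(16 * 0.5938)

    def test_single_voxel_is_zero(self):
        assert metrics.long_diameter(np.array([[3, 3, 1]]), (1, 1, 5)) == 0.0

    def test_empty_component_raises(self):
        with pytest.raises(ValueError):
            metrics.long_diameter(np.zeros((2, 2, 2), bool), (1, 1, 1))

    def test_inplane_restriction(self):
        # two voxels on different slices: far apart in 3D, 0 in-plane
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = mask[0, 0, 3] = True
        assert metrics.long_diameter(mask, (1, 1, 5), mode="inplane") == 0.0
        assert metrics.long_diameter(mask, (1, 1, 5), mode="3d") == pytest.approx(15.0)

    def test_matches_bruteforce_pairwise(self, rng):
        """Hull-accelerated diameter equals the all-pairs maximum."""
        for _ in range(10):
            idx = np.unique(rng.integers(0, 12, (200, 3)), axis=0)
            sp = np.array([0.7, 1.3, 5.0])
            got = metrics.long_diameter(idx, sp, mode="3d")
            pts = idx * sp
            d2 = ((pts[:, None] - pts[None]) ** 2).sum(-1)
            assert got == pytest.approx(np.sqrt(d2.max()))


class TestSizeBin:
    @pytest.mark.parametrize("d,expected", [
        (3.0, "5-10"),       # sub-5 mm folds into the smallest bin
        (5.0, "5-10"),
        (9.999, "5-10"),
        (10.0, "10-30"),
        (29.999, "10-30"),
        (30.0, ">30"),
        (45.0, ">30"),
    ])
    def test_bin_edges(self, d, expected):
        assert metrics.size_bin(d) == expected

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            metrics.size_bin(-1.0)


class TestMatching:
    def test_half_detected(self):
        gt = np.zeros((10, 10, 1), np.int16)
        gt[1:3, 1:3, 0] = 1
        gt[6:8, 6:8, 0] = 2
        pred = np.zeros_like(gt, dtype=bool)
        pred[1:3, 1:3, 0] = True
        lesions = metrics.lesions_from_label(make_labels(gt))
        m = metrics.match_lesions(lesions, pred)
        assert m.recall == pytest.approx(0.5)
        assert m.precision == pytest.approx(1.0)

    def test_perfect_prediction(self):
        gt = np.zeros((10, 10, 1), np.int16)
        gt[1:3, 1:3, 0] = 1
        gt[6:8, 6:8, 0] = 2
        lesions = metrics.lesions_from_label(make_labels(gt))
        m = metrics.match_lesions(lesions, gt > 0)
        assert m.recall == m.precision == m.f1 == 1.0

    def test_bridge_component_assigned_to_larger_overlap(self):
        # one predicted component spanning two GT lesions: the pairing is
        # one-to-one, so the smaller-overlap lesion stays undetected
        gt = np.zeros((12, 3, 1), np.int16)
        gt[0:4, 0, 0] = 1    # 4 voxels
        gt[6:8, 0, 0] = 2    # 2 voxels
        pred = np.zeros_like(gt, dtype=bool)
        pred[0:8, 0, 0] = True  # bridges both
        lesions = metrics.lesions_from_label(make_labels(gt))
        m = metrics.match_lesions(lesions, pred)
        assert len(m.matched_gt) == 1
        assert lesions[0].matched and not lesions[1].matched
        assert m.recall == pytest.approx(0.5)


class TestStratifiedReport:
    def _two_lesion_case(self):
        gt = np.zeros((40, 40, 4), np.int16)
        gt[2:10, 2:10, 1] = 1       # 7 mm at unit spacing
        gt[20:35, 20:35, 2] = 2     # 14 mm
        return make_labels(gt, spacing=(1, 1, 5))

    def test_perfect_prediction_all_ones(self):
        lv = self._two_lesion_case()
        rep = metrics.stratified_report([(lv, lv.binary())])
        sub = rep.per_bin.loc[["5-10", "10-30", "overall"], ["dice", "iou", "f1", "recall"]]
        assert np.allclose(sub.values, 1.0)
        assert rep.overall["vs"] == 1.0

    def test_bin_counts_partition_total(self, small_cohort):
        pairs = [(c.lesion_label, c.lesion_label.binary()) for c in small_cohort[:4]]
        rep = metrics.stratified_report(pairs)
        bins = rep.per_bin.loc[["5-10", "10-30", ">30"], "n_lesions"].sum()
        assert bins == rep.per_bin.loc["overall", "n_lesions"]

    def test_report_matches_direct_per_lesion_metrics(self):
        lv = self._two_lesion_case()
        pred = lv.binary().copy()
        pred[2:6, 2:10, 1] = False  # degrade lesion 1 by half
        rep = metrics.stratified_report([(lv, pred)])
        les = metrics.lesions_from_label(lv)[0]
        # recompute lesion-1 dice directly: pred covers half its voxels
        c = metrics.ConfusionCounts(tp=32, fp=0, fn=32)
        assert rep.per_bin.loc["5-10", "dice"] == pytest.approx(metrics.dice(c))
        assert rep.per_bin.loc["5-10", "recall"] == 1.0  # still touched
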