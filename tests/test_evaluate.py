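import numpy as np
import pytest

from longlesion.io_volumes import LesionMask
from longlesion.evaluate import (
    ConfusionCounts,
    DetectionRules,
    avg_score,
    evaluate_case,
    evaluate_cohort,
    filter_small_lesions,
    lesion_metrics,
    paired_wilcoxon,
    voxel_confusion,
    voxel_metrics,
)

from conftest import random_mask_pair


# --- independent oracles -----------------------------------------------------

def confusion_oracle(pred, gt):
    """Triple-loop voxel counting."""
    tp = fp = fn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            for k in range(pred.shape[2]):
                p, g = pred[i, j, k] > 0, gt[i, j, k] > 0
                tp += p and g
                fp += p and not g
                fn += g and not p
    return tp, fp, fn


def flood_fill_components(mask):
    """Brute-force 26-connected components via BFS."""
    mask = np.asarray(mask) > 0
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    offsets = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
               for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
    for idx in np.argwhere(mask):
        idx = tuple(idx)
        if seen[idx]:
            continue
        stack, comp = [idx], []
        seen[idx] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for o in offsets:
                w = tuple(a + b for a, b in zip(v, o))
                if all(0 <= c < s for c, s in zip(w, mask.shape)) \
                        and mask[w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(comp)
    return comps


def lesion_metrics_oracle(pred, gt, rules):
    """Per-component brute-force application of the detection rules."""
    gt_comps = flood_fill_components(gt)
    pred_comps = flood_fill_components(pred)
    detected = sum(
        (sum(pred[v] > 0 for v in comp) / len(comp)) >= rules.sl_overlap_min
        for comp in gt_comps
    )
    true_pos = 0
    for comp in pred_comps:
        inside = sum(gt[v] > 0 for v in comp) / len(comp)
        outside = sum(gt[v] == 0 for v in comp) / len(comp)
        true_pos += inside >= rules.pl_overlap_min and outside <= rules.pl_outside_max
    sl = None if not gt_comps else detected / len(gt_comps)
    pl = None if not pred_comps else true_pos / len(pred_comps)
    if sl is None or pl is None:
        f1 = None
    elif sl + pl == 0:
        f1 = 0.0
    else:
        f1 = 2 * sl * pl / (sl + pl)
    return sl, pl, f1


# --- voxel metrics -----------------------------------------------------------

class TestVoxelMetrics:
    def test_perfect_prediction(self):
        m = LesionMask((np.arange(27).reshape(3, 3, 3) < 10).astype(np.uint8))
        c = voxel_confusion(m, m)
        assert (c.TP, c.FP, c.FN) == (10, 0, 0)
        v = voxel_metrics(c)
        assert v.dice == v.ppv == v.tpr == 1.0

    def test_empty_prediction(self):
        gt = np.zeros((3, 3, 3), np.uint8)
        gt.flat[:7] = 1
        c = voxel_confusion(LesionMask(np.zeros_like(gt)), LesionMask(gt))
        assert (c.TP, c.FP, c.FN) == (0, 0, 7)
        v = voxel_metrics(c)
        assert v.dice == 0.0 and v.ppv is None and v.tpr == 0.0

    def test_matches_voxel_loop_oracle(self, rng):
        for _ in range(20):
            pred, gt = random_mask_pair(rng, shape=(8, 8, 8), p=0.2)
            c = voxel_confusion(pred, gt)
            assert (c.TP, c.FP, c.FN) == confusion_oracle(pred.data, gt.data)

    def test_worked_counts(self):
        v = voxel_metrics(ConfusionCounts(TP=2, FP=1, FN=1))
        assert v.dice == pytest.approx(2 / 3)
        assert v.ppv == pytest.approx(2 / 3)
        assert v.tpr == pytest.approx(2 / 3)

    def test_both_empty_dice_is_one(self):
        v = voxel_metrics(ConfusionCounts(0, 0, 0))
        assert v.dice == 1.0 and v.ppv is None and v.tpr is None

    def test_dice_is_harmonic_mean_of_ppv_tpr(self, rng):
        for _ in range(1000):
            tp, fp, fn = (int(x) for x in rng.integers(0, 50, 3))
            if tp == 0:
                continue
            v = voxel_metrics(ConfusionCounts(tp, fp, fn))
            hm = 2 * v.ppv * v.tpr / (v.ppv + v.tpr)
            assert abs(v.dice - hm) < 1e-12

    def test_added_true_positive_never_decreases_dice(self, rng):
        pred, gt = random_mask_pair(rng, shape=(8, 8, 8), p=0.2)
        missed = np.argwhere((gt.data > 0) & (pred.data == 0))
        if len(missed) == 0:
            pytest.skip("no missed voxel in draw")
        before = voxel_metrics(voxel_confusion(pred, gt))
        new = pred.data.copy()
        new[tuple(missed[0])] = 1
        after = voxel_metrics(voxel_confusion(LesionMask(new), gt))
        assert after.dice >= before.dice and after.tpr >= before.tpr


# --- small-lesion filter -----------------------------------------------------

class TestFilter:
    def _mask(self, voxels, shape=(10, 10, 10), spacing=(1, 1, 1)):
        m = np.zeros(shape, np.uint8)
        for v in voxels:
            m[v] = 1
        return LesionMask(m, spacing)

    def test_two_voxel_component_removed_at_1mm(self):
        m = self._mask([(1, 1, 1), (1, 1, 2)])
        out = filter_small_lesions(m)  # 2 mm^3 < 3 mm^3
        assert out.n_voxels == 0

    def test_three_voxel_component_kept_tie(self):
        m = self._mask([(1, 1, 1), (1, 1, 2), (1, 1, 3)])
        out = filter_small_lesions(m)  # exactly 3 mm^3: ties kept
        assert out.n_voxels == 3

    def test_empty_mask(self):
        out = filter_small_lesions(self._mask([]))
        assert out.n_voxels == 0

    def test_spacing_scales_volume(self):
        # one voxel of 2x2x1 mm = 4 mm^3 >= 3 mm^3
        m = self._mask([(1, 1, 1)], spacing=(2, 2, 1))
        assert filter_small_lesions(m).n_voxels == 1

    def test_idempotent(self, rng):
        pred, _ = random_mask_pair(rng, shape=(12, 12, 12), p=0.15)
        once = filter_small_lesions(pred)
        twice = filter_small_lesions(once)
        assert np.array_equal(once.data, twice.data)


# --- lesion metrics ----------------------------------------------------------

class TestLesionMetrics:
    def test_identical_masks(self, rng):
        m = np.zeros((20, 20, 20), np.uint8)
        m[2:5, 2:5, 2:5] = 1
        m[10:14, 10:14, 10:14] = 1
        m[2:4, 15:18, 15:18] = 1
        lm = lesion_metrics(LesionMask(m), LesionMask(m))
        assert lm.SL == lm.PL == lm.les_f1 == 1.0

    def test_ten_percent_boundary_detection(self):
        """A 20-voxel gt lesion with 2 covered voxels sits exactly at the 10%
        sensitivity boundary; the 2-voxel prediction is fully inside gt."""
        gt = np.zeros((10, 10, 10), np.uint8)
        gt[1:5, 1:6, 1] = 1  # 20 voxels
        pred = np.zeros_like(gt)
        pred[1, 1:3, 1] = 1  # 2 of them, nothing else
        lm = lesion_metrics(LesionMask(pred), LesionMask(gt))
        assert lm.SL == 1.0  # 0.10 >= 0.10
        assert lm.PL == 1.0  # fully inside
        assert lm.les_f1 == 1.0

    def test_pl_rules_reject_mostly_outside_prediction(self):
        gt = np.zeros((10, 10, 10), np.uint8)
        gt[1:3, 1:3, 1] = 1  # 4 voxels
        pred = np.zeros_like(gt)
        pred[1:3, 1:6, 1] = 1  # 10 voxels, 4 inside (40% < 65%)
        lm = lesion_metrics(LesionMask(pred), LesionMask(gt))
        assert lm.PL == 0.0
        assert lm.SL == 1.0  # gt fully covered

    def test_harmonic_mean_of_equal_values(self):
        gt = np.zeros((14, 14, 6), np.uint8)
        gt[1:3, 1:3, 1] = 1     # detected & matched
        gt[8:10, 8:10, 1] = 1   # missed
        pred = np.zeros_like(gt)
        pred[1:3, 1:3, 1] = 1   # true positive
        pred[8:10, 1:3, 4] = 1  # false positive far away
        lm = lesion_metrics(LesionMask(pred), LesionMask(gt))
        assert lm.SL == 0.5 and lm.PL == 0.5
        assert lm.les_f1 == pytest.approx(0.5)

    def test_matches_componentwise_oracle(self, rng):
        rules = DetectionRules()
        for _ in range(30):
            pred, gt = random_mask_pair(rng, shape=(10, 10, 10), p=0.12)
            lm = lesion_metrics(pred, gt, rules)
            sl, pl, f1 = lesion_metrics_oracle(pred.data, gt.data, rules)
            assert lm.SL == sl and lm.PL == pl
            if f1 is None:
                assert lm.les_f1 is None
            else:
                assert lm.les_f1 == pytest.approx(f1, abs=1e-12)

    def test_empty_gt_flags_undefined(self):
        pred = LesionMask(np.zeros((5, 5, 5), np.uint8))
        lm = lesion_metrics(pred, LesionMask(np.zeros((5, 5, 5), np.uint8)))
        assert lm.SL is None and lm.PL is None and lm.les_f1 is None


class TestAggregateScore:
    def test_worked_values(self):
        from longlesion.evaluate import LesionMetrics, VoxelMetrics

        assert avg_score(VoxelMetrics(1.0, 1, 1), LesionMetrics(1, 1, 1.0)) == 1.0
        assert avg_score(VoxelMetrics(0.514, None, None),
                         LesionMetrics(None, None, 0.573)) == pytest.approx(0.5435)
        assert avg_score(VoxelMetrics(0.0, None, None),
                         LesionMetrics(None, None, 0.8)) == pytest.approx(0.4)

    def test_undefined_propagates(self):
        from longlesion.evaluate import LesionMetrics, VoxelMetrics

        assert avg_score(VoxelMetrics(None, None, None),
                         LesionMetrics(1, 1, 1.0)) is None


class TestWilcoxon:
    def test_identical_lists_degenerate(self):
        a = [0.5, 0.6, 0.7, 0.8, 0.4, 0.3]
        stat, p, info = paired_wilcoxon(a, a)
        assert p == 1.0 and info["degenerate"] and not info["significant"]

    def test_uniform_shift_exact_p(self):
        """n=10 all-positive differences: two-sided exact p = 2/2^10."""
        rng = np.random.default_rng(0)
        b = rng.random(10)
        a = b + 0.1
        stat, p, info = paired_wilcoxon(a, b)
        assert p == pytest.approx(2 / 2**10)
        assert info["significant"]

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(1)
        a = rng.random(12)
        b = a + rng.normal(0, 0.1, 12)
        _, p1, _ = paired_wilcoxon(a, b)
        _, p2, _ = paired_wilcoxon(b, a)
        assert p1 == pytest.approx(p2)

    def test_short_lists_rejected(self):
        with pytest.raises(ValueError):
            paired_wilcoxon([1, 2, 3], [1, 2, 4])


class TestCohort:
    def test_case_pipeline_filters_then_scores(self, rng):
        gt = np.zeros((16, 16, 16), np.uint8)
        gt[4:8, 4:8, 4:8] = 1
        noise = gt.copy()
        noise[0, 0, 0] = 1  # 1 mm^3 speck must be filtered out of pred
        res = evaluate_case(LesionMask(noise), LesionMask(gt))
        assert res.voxel.dice == 1.0 and res.avg == 1.0

    def test_cohort_means_exclude_undefined(self, rng):
        m1 = LesionMask((rng.random((10, 10, 10)) < 0.2).astype(np.uint8))
        empty = LesionMask(np.zeros((10, 10, 10), np.uint8))
        report = evaluate_cohort([(m1, m1), (empty, empty)])
        assert report.n_excluded == 1
        assert report.mean_avg == pytest.approx(1.0)
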