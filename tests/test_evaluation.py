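"""Evaluation metrics against independent brute-force oracles and printed values."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctaseg.evaluation import (
    RegionContingency,
    aspects_score,
    combined_dsc,
    largest_component_volume,
    metrics_from_contingency,
    region_contingency,
    region_positivity,
    roc_curve,
    round_half_up,
    threshold_map,
    voxel_metrics,
)
from ctaseg.grid import (
    BinaryMask,
    ImageVolume,
    ParameterError,
    ProbabilityMap,
    RegionAtlas,
    aspects_label_table,
)


def _pmap(values, mask_arr=None):
    vol = ImageVolume(np.asarray(values, dtype=float))
    if mask_arr is None:
        mask_arr = np.ones(vol.shape, dtype=np.uint8)
    mask = BinaryMask.from_array(mask_arr, vol)
    return ProbabilityMap(vol.with_values(vol.values * mask.as_bool()), mask), mask


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def concordance_auc(scores, labels):
    """O(n^2) pairwise-ranking AUC with ties counted half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return wins / (len(pos) * len(neg))


def flood_fill_components(arr):
    """BFS 26-connected component sizes, independent of scipy labelling."""
    arr = np.asarray(arr, dtype=bool)
    seen = np.zeros_like(arr)
    sizes = []
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
               if (i, j, k) != (0, 0, 0)]
    for start in map(tuple, np.argwhere(arr)):
        if seen[start]:
            continue
        stack, size = [start], 0
        seen[start] = True
        while stack:
            v = stack.pop()
            size += 1
            for off in offsets:
                w = tuple(a + b for a, b in zip(v, off))
                if all(0 <= wi < si for wi, si in zip(w, arr.shape)) and arr[w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
        sizes.append(size)
    return sizes


class TestThresholdMap:
    def test_tie_rule_positive_at_threshold(self):
        pmap, _ = _pmap(np.array([0.49, 0.5, 0.51]).reshape(3, 1, 1))
        out = threshold_map(pmap, 0.5)
        assert out.values.ravel().tolist() == [0, 1, 1]

    def test_extreme_thresholds(self):
        arr = np.array([0.0, 0.3, 0.9]).reshape(3, 1, 1)
        pmap, mask = _pmap(arr)
        assert threshold_map(pmap, 0.0).n_positive == mask.n_positive
        assert threshold_map(pmap, 1.0).n_positive == 0  # max < 1

    def test_out_of_range_threshold_rejected(self):
        pmap, _ = _pmap(np.zeros((2, 2, 2)))
        with pytest.raises(ParameterError):
            threshold_map(pmap, 1.5)


class TestVoxelMetrics:
    def _masks(self, pred_arr, truth_arr):
        vol = ImageVolume(np.zeros(pred_arr.shape))
        full = BinaryMask.from_array(np.ones(pred_arr.shape), vol)
        return (BinaryMask.from_array(pred_arr, vol),
                BinaryMask.from_array(truth_arr, vol), full)

    def test_perfect_overlap(self):
        arr = np.zeros((4, 4, 4))
        arr[1:3, 1:3, 1:3] = 1
        vm = voxel_metrics(*self._masks(arr, arr))
        assert vm.dsc == 1.0 and vm.sensitivity == 1.0

    def test_disjoint_nonempty(self):
        a = np.zeros((4, 4, 4))
        b = np.zeros((4, 4, 4))
        a[0, 0, 0] = 1
        b[3, 3, 3] = 1
        assert voxel_metrics(*self._masks(a, b)).dsc == 0.0

    def test_empty_truth_conventions(self):
        zero = np.zeros((3, 3, 3))
        one = zero.copy()
        one[0, 0, 0] = 1
        vm = voxel_metrics(*self._masks(zero, zero))
        assert np.isnan(vm.sensitivity) and vm.dsc == 1.0
        vm2 = voxel_metrics(*self._masks(one, zero))
        assert vm2.dsc == 0.0 and vm2.undefined_reason is not None

    def test_matches_bruteforce_recount_on_random_masks(self):
        gen = np.random.default_rng(42)
        for _ in range(5):
            pred = (gen.random((20, 20, 20)) < 0.3).astype(np.uint8)
            truth = (gen.random((20, 20, 20)) < 0.1).astype(np.uint8)
            mask = (gen.random((20, 20, 20)) < 0.8).astype(np.uint8)
            vol = ImageVolume(np.zeros((20, 20, 20)))
            vm = voxel_metrics(BinaryMask.from_array(pred, vol),
                               BinaryMask.from_array(truth, vol),
                               BinaryMask.from_array(mask, vol))
            # voxel-by-voxel recount
            tp = fp = fn = tn = 0
            for i in range(20):
                for j in range(20):
                    for k in range(20):
                        if not mask[i, j, k]:
                            continue
                        p, t = bool(pred[i, j, k]), bool(truth[i, j, k])
                        tp += p and t
                        fp += p and not t
                        fn += (not p) and t
                        tn += (not p) and (not t)
            assert vm.sensitivity == pytest.approx(tp / (tp + fn), abs=1e-12)
            assert vm.specificity == pytest.approx(tn / (tn + fp), abs=1e-12)
            assert vm.dsc == pytest.approx(2 * tp / (2 * tp + fp + fn), abs=1e-12)


class TestRocCurve:
    def test_perfect_scores_auc_one(self):
        truth_arr = (np.arange(27) % 2).reshape(3, 3, 3).astype(np.uint8)
        pmap, mask = _pmap(truth_arr.astype(float))
        truth = BinaryMask.from_array(truth_arr, pmap.volume)
        curve = roc_curve(pmap, truth, mask)
        assert curve.auc == pytest.approx(1.0)
        assert curve.fpr[0] == 0.0 and curve.fpr[-1] == 1.0
        assert np.all(np.diff(curve.fpr) >= 0)

    def test_random_scores_auc_near_half(self):
        gen = np.random.default_rng(0)
        scores = gen.random((12, 12, 12))
        truth_arr = (gen.random((12, 12, 12)) < 0.3).astype(np.uint8)
        pmap, mask = _pmap(scores)
        truth = BinaryMask.from_array(truth_arr, pmap.volume)
        assert abs(roc_curve(pmap, truth, mask).auc - 0.5) < 0.05

    def test_single_class_truth_rejected(self):
        pmap, mask = _pmap(np.random.default_rng(1).random((3, 3, 3)))
        empty = BinaryMask.from_array(np.zeros((3, 3, 3)), pmap.volume)
        with pytest.raises(ParameterError):
            roc_curve(pmap, empty, mask)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 10_000), st.integers(2, 6))
    def test_auc_equals_concordance_estimator(self, seed, quant):
        gen = np.random.default_rng(seed)
        scores = np.round(gen.random((6, 6, 6)), quant)  # ties at coarse quantization
        truth_arr = (gen.random((6, 6, 6)) < 0.4).astype(np.uint8)
        if truth_arr.min() == truth_arr.max():
            return
        pmap, mask = _pmap(scores)
        truth = BinaryMask.from_array(truth_arr, pmap.volume)
        auc = roc_curve(pmap, truth, mask).auc
        oracle = concordance_auc(scores.ravel(), truth_arr.ravel())
        assert abs(auc - oracle) < 1e-9


def _atlas(shape=(10, 6, 4)):
    """Toy atlas: left labels 1-10 at x<mid, right 11-20 at x>=mid."""
    arr = np.zeros(shape, dtype=np.int16)
    half = shape[0] // 2
    for side, sl in ((0, slice(0, half)), (10, slice(half, None))):
        block = arr[sl]
        flat = np.arange(block.size) % 10 + 1 + side
        arr[sl] = flat.reshape(block.shape)
    vol = ImageVolume(arr.astype(float))
    return RegionAtlas(vol.with_values(arr)), vol


class TestRegionPositivity:
    def test_empty_prediction_all_negative(self):
        atlas, vol = _atlas()
        pred = BinaryMask.from_array(np.zeros(vol.shape), vol)
        assert not region_positivity(pred, atlas).any()

    def test_single_voxel_marks_exactly_one_region(self):
        atlas, vol = _atlas()
        label = int(atlas.values[2, 3, 1])
        pred_arr = np.zeros(vol.shape)
        pred_arr[2, 3, 1] = 1
        pos = region_positivity(BinaryMask.from_array(pred_arr, vol), atlas)
        assert pos.sum() == 1
        assert pos[label - 1]

    def test_matches_bruteforce_intersection(self):
        atlas, vol = _atlas()
        gen = np.random.default_rng(3)
        pred_arr = (gen.random(vol.shape) < 0.05).astype(np.uint8)
        pos = region_positivity(BinaryMask.from_array(pred_arr, vol), atlas)
        for lab in range(1, 21):
            expected = bool(np.any(pred_arr.astype(bool) & (atlas.values == lab)))
            assert pos[lab - 1] == expected

    def test_monotone_in_added_voxels(self):
        atlas, vol = _atlas()
        gen = np.random.default_rng(4)
        a = (gen.random(vol.shape) < 0.02).astype(np.uint8)
        b = np.clip(a + (gen.random(vol.shape) < 0.05), 0, 1).astype(np.uint8)
        pos_a = region_positivity(BinaryMask.from_array(a, vol), atlas)
        pos_b = region_positivity(BinaryMask.from_array(b, vol), atlas)
        assert np.all(pos_b | ~pos_a)  # a-positive regions stay positive

    def test_missing_label_warns_and_counts_negative(self):
        arr = np.zeros((6, 6, 6), dtype=np.int16)
        arr[:3] = 1  # only label 1 present
        vol = ImageVolume(arr.astype(float))
        atlas = RegionAtlas(vol.with_values(arr))
        pred = BinaryMask.from_array(np.zeros(arr.shape), vol)
        with pytest.warns(UserWarning, match="absent"):
            pos = region_positivity(pred, atlas)
        assert not pos.any()


class TestRegionContingency:
    def test_identical_vectors(self):
        vecs = np.zeros((3, 20), dtype=bool)
        vecs[:, :4] = True  # 12 positives over 3 cases
        c = region_contingency(vecs, vecs)
        assert (c.tp, c.fn, c.fp, c.tn) == (12, 0, 0, 48)
        assert c.total == 60

    def test_all_negative_truth_counts_fp(self):
        pred = np.zeros((1, 20), dtype=bool)
        pred[0, :7] = True
        c = region_contingency(pred, np.zeros((1, 20), dtype=bool))
        assert c.fp == 7 and c.tp == 0

    def test_matches_bruteforce_tally(self):
        gen = np.random.default_rng(9)
        pred = gen.random((8, 20)) < 0.4
        truth = gen.random((8, 20)) < 0.3
        c = region_contingency(pred, truth)
        tp = sum(bool(p) and bool(t) for p, t in zip(pred.ravel(), truth.ravel()))
        fp = sum(bool(p) and not t for p, t in zip(pred.ravel(), truth.ravel()))
        fn = sum(not p and bool(t) for p, t in zip(pred.ravel(), truth.ravel()))
        assert (c.tp, c.fp, c.fn) == (tp, fp, fn)
        assert c.total == 160

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            region_contingency(np.zeros((1, 20), bool), np.zeros((1, 19), bool))


class TestContingencyMetrics:
    # printed region counts of the three feature-set rows: (tn, tp, fn, fp,
    # fp_group_b) -> printed sensitivity/specificity/DSC/combined DSC
    ROWS = [
        ((78, 99, 6, 117), 92, 0.94, 0.40, 0.62, 0.48),
        ((158, 98, 7, 37), 46, 0.93, 0.81, 0.82, 0.69),
        ((159, 98, 7, 36), 34, 0.93, 0.82, 0.82, 0.72),
    ]

    @pytest.mark.parametrize("counts,fp_b,sens,spec,dsc,cdsc", ROWS)
    def test_reproduces_printed_metrics(self, counts, fp_b, sens, spec, dsc, cdsc):
        tn, tp, fn, fp = counts
        c = RegionContingency(tn=tn, tp=tp, fn=fn, fp=fp)
        m = metrics_from_contingency(c)
        assert m["sensitivity_2dp"] == sens
        assert m["specificity_2dp"] == spec
        assert m["dsc_2dp"] == dsc
        assert round_half_up(combined_dsc(c, fp_b)) == cdsc

    def test_undefined_on_zero_denominator(self):
        m = metrics_from_contingency(RegionContingency(tn=300))
        assert m["specificity"] == 1.0
        assert np.isnan(m["sensitivity"])
        assert np.isnan(combined_dsc(RegionContingency(), 0))

    def test_combined_reduces_to_group_a_without_b_fp(self):
        c = RegionContingency(tn=10, tp=5, fn=2, fp=3)
        assert combined_dsc(c, 0) == pytest.approx(metrics_from_contingency(c)["dsc"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ParameterError):
            RegionContingency(tn=-1)


class TestAspectsScore:
    def test_all_negative_full_score(self):
        assert aspects_score(np.zeros(20, bool)) == 10

    def test_worst_hemisphere_reported(self):
        v = np.zeros(20, bool)
        v[[0, 1, 2]] = True  # three left-hemisphere regions positive
        assert aspects_score(v) == 7

    def test_all_positive_zero(self):
        assert aspects_score(np.ones(20, bool)) == 0

    def test_weakly_decreasing_as_regions_added(self):
        gen = np.random.default_rng(5)
        v = np.zeros(20, bool)
        prev = aspects_score(v)
        for idx in gen.permutation(20):
            v[idx] = True
            cur = aspects_score(v)
            assert cur <= prev
            prev = cur

    def test_wrong_length_rejected(self):
        with pytest.raises(ParameterError):
            aspects_score(np.zeros(10, bool))


class TestLargestComponentVolume:
    def test_cube_at_unit_spacing(self):
        arr = np.zeros((20, 20, 20))
        arr[5:15, 5:15, 5:15] = 1
        vol = ImageVolume(arr)
        assert largest_component_volume(BinaryMask.from_array(arr, vol)) == pytest.approx(1.0)

    def test_largest_of_two_components(self):
        arr = np.zeros((30, 10, 10))
        arr[0:4, 0:5, 0:5] = 1  # 100 voxels
        arr[20:22, 0:5, 0:5] = 1  # 50 voxels
        vol = ImageVolume(arr, spacing_mm=(1, 1, 1))
        assert largest_component_volume(BinaryMask.from_array(arr, vol)) == pytest.approx(0.1)

    def test_empty_mask_zero(self):
        vol = ImageVolume(np.zeros((5, 5, 5)))
        assert largest_component_volume(BinaryMask.from_array(np.zeros((5, 5, 5)), vol)) == 0.0

    def test_matches_flood_fill_oracle(self):
        gen = np.random.default_rng(8)
        arr = (gen.random((15, 15, 15)) < 0.2).astype(np.uint8)
        vol = ImageVolume(arr.astype(float), spacing_mm=(2, 2, 2))
        got = largest_component_volume(BinaryMask.from_array(arr, vol))
        expected = max(flood_fill_components(arr)) * 8.0 / 1000.0
        assert got == pytest.approx(expected, abs=1e-12)


def test_round_half_up_ties_away_from_zero():
    assert round_half_up(0.815) == 0.82
    assert round_half_up(0.405) == 0.41
    assert round_half_up(0.62499) == 0.62
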