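"""The seven segmentation metrics against hand counts and brute force."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lymphseg import (
    BinaryMask3D,
    average_distance,
    degrade_mask,
    hausdorff_distance,
    mahalanobis_distance,
    overlap_scores,
    score_pair,
    voxel_confusion,
)
from lymphseg.metrics import VoxelConfusion

from .oracles import average_bruteforce, hausdorff_bruteforce


def _mask(data, spacing=(1.0, 1.0, 1.0)):
    return BinaryMask3D(np.asarray(data, dtype=np.uint8), spacing)


class TestConfusion:
    def test_identity(self, rng):
        data = np.zeros((5, 5, 5), dtype=np.uint8)
        data[tuple(rng.integers(0, 5, size=(3, 10)))] = 1
        m = _mask(data)
        c = voxel_confusion(m, m)
        assert c.fp == c.fn == 0
        assert c.tp == int(data.sum())

    def test_complement(self):
        data = np.zeros((3, 3, 3), dtype=np.uint8)
        data[0] = 1
        c = voxel_confusion(_mask(data), _mask(1 - data))
        assert c.tp == 0 and c.tn == 0

    def test_hand_counted_toy(self):
        pred = np.zeros((1, 2, 3), dtype=np.uint8)
        ref = np.zeros((1, 2, 3), dtype=np.uint8)
        pred[0, 0, :2] = 1
        pred[0, 1, 0] = 1          # extra
        ref[0, 0, :2] = 1
        ref[0, 1, 2] = 1           # missed
        c = voxel_confusion(_mask(pred), _mask(ref))
        assert (c.tp, c.fp, c.fn) == (2, 1, 1)

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            voxel_confusion(_mask(np.zeros((2, 2, 2))),
                            _mask(np.zeros((3, 2, 2))))


class TestOverlapScores:
    def test_hand_arithmetic(self):
        dice, ppv, tpr, vs = overlap_scores(VoxelConfusion(2, 1, 10, 1))
        assert dice == pytest.approx(2 / 3)
        assert ppv == pytest.approx(2 / 3)
        assert tpr == pytest.approx(2 / 3)
        assert vs == pytest.approx(1.0)  # FP == FN

    def test_no_overlap(self):
        dice, _, _, vs = overlap_scores(VoxelConfusion(0, 3, 10, 1))
        assert dice == 0
        assert vs == pytest.approx(0.5)

    def test_perfect(self):
        assert overlap_scores(VoxelConfusion(7, 0, 3, 0)) == (1, 1, 1, 1)

    def test_undefined_marked_none(self):
        dice, ppv, tpr, vs = overlap_scores(VoxelConfusion(0, 0, 10, 0))
        assert dice is None and ppv is None and tpr is None and vs is None

    def test_vs_one_for_disjoint_equal_masks(self):
        # documented quirk: VS compares volumes only
        pred = np.zeros((2, 2, 2), dtype=np.uint8)
        ref = np.zeros((2, 2, 2), dtype=np.uint8)
        pred[0, 0, 0] = 1
        ref[1, 1, 1] = 1
        _, _, _, vs = overlap_scores(voxel_confusion(_mask(pred), _mask(ref)))
        assert vs == pytest.approx(1.0)

    @settings(max_examples=100, deadline=None)
    @given(tp=st.integers(1, 500), fp=st.integers(0, 500),
           fn=st.integers(0, 500))
    def test_dice_is_harmonic_mean_of_ppv_tpr(self, tp, fp, fn):
        dice, ppv, tpr, _ = overlap_scores(VoxelConfusion(tp, fp, 1, fn))
        assert dice == pytest.approx(2 * ppv * tpr / (ppv + tpr))


class TestDistances:
    def test_identity_zero(self, rng):
        a = rng.normal(size=(10, 3))
        assert hausdorff_distance(a, a) == 0
        assert average_distance(a, a) == 0
        assert mahalanobis_distance(a, a) == 0

    def test_single_pair(self):
        assert hausdorff_distance([[0, 0, 0]], [[0, 0, 3]]) == 3

    def test_directed_asymmetry_resolved_by_max(self):
        a = [[0, 0, 0], [0, 0, 10]]
        b = [[0, 0, 0]]
        assert hausdorff_distance(a, b) == 10
        assert average_distance(a, b) == pytest.approx(5.0)

    def test_average_example(self):
        assert average_distance([[0, 0, 0], [0, 0, 2]], [[0, 0, 0]]) == 1

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            hausdorff_distance(np.empty((0, 3)), [[0, 0, 0]])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(scale=5, size=(rng.integers(1, 50), 3))
        b = rng.normal(scale=5, size=(rng.integers(1, 50), 3))
        assert hausdorff_distance(a, b) == pytest.approx(
            hausdorff_bruteforce(a, b), abs=1e-12
        )
        assert average_distance(a, b) == pytest.approx(
            average_bruteforce(a, b), abs=1e-9
        )

    def test_avd_not_above_hd(self, rng):
        for _ in range(20):
            a = rng.normal(size=(20, 3))
            b = rng.normal(size=(15, 3))
            assert average_distance(a, b) <= hausdorff_distance(a, b) + 1e-12


class TestMahalanobis:
    def test_identity_covariance_reduces_to_euclidean(self, rng):
        a = rng.normal(size=(200, 3))
        # whiten so the sample covariance is exactly identity
        a = (a - a.mean(axis=0)) @ np.linalg.inv(
            np.linalg.cholesky(np.cov(a, rowvar=False)).T
        )
        b = a + np.array([3.0, 0.0, 0.0])
        assert mahalanobis_distance(a, b) == pytest.approx(3.0, abs=1e-6)

    def test_affine_invariance(self, rng):
        a = rng.normal(size=(40, 3))
        b = rng.normal(size=(30, 3)) + 2.0
        m = rng.normal(size=(3, 3)) + np.eye(3) * 2
        d0 = mahalanobis_distance(a, b)
        d1 = mahalanobis_distance(a @ m.T, b @ m.T)
        assert d1 == pytest.approx(d0, abs=1e-6)

    def test_nonnegative_zero_iff_equal_means(self, rng):
        a = rng.normal(size=(30, 3))
        b = a - a.mean(axis=0) + a.mean(axis=0)  # same mean
        assert mahalanobis_distance(a, b) == pytest.approx(0, abs=1e-9)


class TestScorePair:
    def test_identical_masks(self, clean_phantom):
        _, mask, _ = clean_phantom
        s = score_pair(mask, mask)
        assert s.dice == s.ppv == s.tpr == s.vs == 1
        assert s.hd_mm == s.avd_mm == 0
        assert s.mhd_mm == pytest.approx(0, abs=1e-9)

    def test_one_voxel_translation_hd(self):
        pred = np.zeros((6, 6, 6), dtype=np.uint8)
        ref = np.zeros((6, 6, 6), dtype=np.uint8)
        pred[2:4, 2:4, 2:4] = 1
        ref[1:3, 2:4, 2:4] = 1
        s = score_pair(_mask(pred), _mask(ref))
        assert s.hd_mm == pytest.approx(1.0)

    def test_symmetry(self, clean_phantom):
        _, mask, _ = clean_phantom
        deg = degrade_mask(mask, 0.3, 0.0, seed=3)
        s1 = score_pair(deg, mask)
        s2 = score_pair(mask, deg)
        assert s1.dice == pytest.approx(s2.dice)
        assert s1.hd_mm == pytest.approx(s2.hd_mm)
        assert s1.avd_mm == pytest.approx(s2.avd_mm)
        assert s1.mhd_mm == pytest.approx(s2.mhd_mm, abs=1e-9)

    def test_empty_pred_distances_none_scores_defined(self, clean_phantom):
        _, mask, _ = clean_phantom
        empty = _mask(np.zeros(mask.shape), mask.spacing)
        s = score_pair(empty, mask)
        assert s.dice == 0 and s.tpr == 0 and s.ppv is None
        assert s.hd_mm is None and s.avd_mm is None and s.mhd_mm is None

    def test_degradation_monotonic_on_average(self, clean_phantom):
        _, mask, _ = clean_phantom
        dices, hds = [], []
        for rate in (0.1, 0.4):
            ds, hs = [], []
            for seed in range(5):
                deg = degrade_mask(mask, rate, 0.0, seed=seed)
                s = score_pair(deg, mask)
                ds.append(s.dice)
                hs.append(s.hd_mm)
            dices.append(np.mean(ds))
            hds.append(np.mean(hs))
        assert dices[0] > dices[1]
        assert hds[0] <= hds[1]


class TestPerLesionScoring:
    def test_matched_pairs_scored_in_isolation(self):
        from lymphseg import label_components, score_lesion_pairs

        pred = np.zeros((4, 16, 16), dtype=np.uint8)
        ref = np.zeros((4, 16, 16), dtype=np.uint8)
        # pair 1: perfect overlap; a distant unrelated pair must not dilute it
        pred[1, 1:4, 1:4] = ref[1, 1:4, 1:4] = 1
        # pair 2: half overlap
        ref[2, 10:14, 10:14] = 1
        pred[2, 10:14, 12:14] = 1
        pairs = score_lesion_pairs(
            label_components(_mask(pred)), label_components(_mask(ref))
        )
        assert len(pairs) == 2
        by_ref = {r: s for _, r, s in pairs}
        perfect = [s for s in by_ref.values() if s.dice == 1]
        partial = [s for s in by_ref.values() if s.dice < 1]
        assert len(perfect) == 1 and len(partial) == 1
        assert partial[0].dice == pytest.approx(2 * 8 / (8 + 16))
        assert perfect[0].hd_mm == 0
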