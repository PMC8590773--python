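"""Detection matching, patient-level statistics, agreement measures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lymphseg import (
    BinaryMask3D,
    PatientOutcome,
    bland_altman,
    cohens_kappa,
    detection_scores,
    label_components,
    match_lesions,
    patient_level_scores,
    pearson_r,
)
from lymphseg.evaluate import DetectionResult


def _lesions(data, spacing=(1.0, 1.0, 1.0)):
    return label_components(
        BinaryMask3D(np.asarray(data, dtype=np.uint8), spacing)
    )


class TestMatchLesions:
    def test_single_voxel_overlap_counts(self):
        pred = np.zeros((5, 8, 8), dtype=np.uint8)
        ref = np.zeros((5, 8, 8), dtype=np.uint8)
        ref[2, 2:5, 2:5] = 1
        pred[2, 4:7, 4:7] = 1  # shares exactly voxel (2,4,4)
        r = match_lesions(_lesions(pred), _lesions(ref))
        assert (r.tp, r.fp, r.fn) == (1, 0, 0)

    def test_disjoint_prediction_is_fp(self):
        pred = np.zeros((5, 8, 8), dtype=np.uint8)
        ref = np.zeros((5, 8, 8), dtype=np.uint8)
        ref[1, 1, 1] = 1
        pred[3, 6, 6] = 1
        r = match_lesions(_lesions(pred), _lesions(ref))
        assert (r.tp, r.fp, r.fn) == (0, 1, 1)

    def test_one_prediction_spanning_two_references(self):
        pred = np.zeros((3, 4, 12), dtype=np.uint8)
        ref = np.zeros((3, 4, 12), dtype=np.uint8)
        ref[1, 1:3, 1:4] = 1
        ref[1, 1:3, 8:11] = 1
        pred[1, 1:3, 1:11] = 1  # one component crossing both
        r = match_lesions(_lesions(pred), _lesions(ref))
        assert (r.tp, r.fp, r.fn) == (2, 0, 0)

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            match_lesions(_lesions(np.zeros((2, 2, 2))),
                          _lesions(np.zeros((3, 2, 2))))

    @pytest.mark.parametrize("seed", range(5))
    def test_counts_match_bruteforce_recount(self, seed):
        rng = np.random.default_rng(seed)
        pred = (rng.random((8, 16, 16)) < 0.08).astype(np.uint8)
        ref = (rng.random((8, 16, 16)) < 0.08).astype(np.uint8)
        pl, rl = _lesions(pred), _lesions(ref)
        r = match_lesions(pl, rl)
        tp = sum(
            1 for lr in rl.lesions
            if np.any((rl.labels == lr.label_id) & (pl.labels > 0))
        )
        fp = sum(
            1 for lp in pl.lesions
            if not np.any((pl.labels == lp.label_id) & (rl.labels > 0))
        )
        fn = rl.n_lesions - tp
        assert (r.tp, r.fp, r.fn) == (tp, fp, fn)
        if tp + fp:
            assert r.precision == pytest.approx(tp / (tp + fp))
        if tp + fn:
            assert r.recall == pytest.approx(tp / (tp + fn))


class TestDetectionScores:
    def test_ratios(self):
        r = detection_scores(DetectionResult([], tp=9, fp=1, fn=3))
        assert r.precision == pytest.approx(0.9)
        assert r.recall == pytest.approx(0.75)
        assert r.f1 == pytest.approx(2 * 0.9 * 0.75 / 1.65)

    def test_degenerate_zero_tp(self):
        r = detection_scores(DetectionResult([], tp=0, fp=2, fn=3))
        assert r.precision == 0 and r.recall == 0
        assert r.f1 == 0 and r.degenerate

    def test_undefined_denominators(self):
        r = detection_scores(DetectionResult([], tp=0, fp=0, fn=3))
        assert r.precision is None
        assert r.f1 == 0 and r.degenerate


class TestPatientLevel:
    def test_all_correct(self):
        outs = [PatientOutcome(True, True)] * 3 + [PatientOutcome(False, False)] * 3
        assert patient_level_scores(outs) == (1.0, 1.0, 1.0)

    def test_balanced_errors_give_chance_auc(self):
        outs = (
            [PatientOutcome(True, True)] * 2 + [PatientOutcome(True, False)] * 2
            + [PatientOutcome(False, False)] * 2 + [PatientOutcome(False, True)] * 2
        )
        sens, spec, auc = patient_level_scores(outs)
        assert sens == spec == auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            patient_level_scores([PatientOutcome(True, True)])

    def test_auc_is_balanced_accuracy(self, rng):
        outs = [
            PatientOutcome(bool(t), bool(p))
            for t, p in rng.integers(0, 2, size=(50, 2))
        ]
        if not any(o.truth_positive for o in outs):
            outs.append(PatientOutcome(True, True))
        if all(o.truth_positive for o in outs):
            outs.append(PatientOutcome(False, True))
        sens, spec, auc = patient_level_scores(outs)
        assert auc == pytest.approx((sens + spec) / 2)
        assert 0 <= sens <= 1 and 0 <= spec <= 1


class TestKappa:
    def test_perfect_agreement(self):
        r = cohens_kappa(["N0", "N1", "N0", "N1"], ["N0", "N1", "N0", "N1"])
        assert r.kappa == pytest.approx(1.0)

    def test_hand_arithmetic_2x2(self):
        # agreement table rows a=(20,5) / (10,15): po=0.7, pe=0.5
        a = ["x"] * 25 + ["y"] * 25
        b = ["x"] * 20 + ["y"] * 5 + ["x"] * 10 + ["y"] * 15
        r = cohens_kappa(a, b)
        assert r.observed_agreement == pytest.approx(0.7)
        assert r.expected_agreement == pytest.approx(0.5)
        assert r.kappa == pytest.approx(0.4)

    def test_constant_rater_zero_kappa(self):
        # po equals pe when one rater is constant
        a = ["x", "x", "y", "y"]
        b = ["x", "x", "x", "x"]
        r = cohens_kappa(a, b)
        assert r.kappa == pytest.approx(0.0)

    def test_undefined_when_expected_agreement_is_one(self):
        r = cohens_kappa(["x", "x"], ["x", "x"])
        assert r.kappa is None

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cohens_kappa(["x"], ["x", "y"])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sklearn(self, seed):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 3, size=60)
        b = rng.integers(0, 3, size=60)
        r = cohens_kappa(a, b)
        assert r.kappa == pytest.approx(
            sklearn_metrics.cohen_kappa_score(a, b), abs=1e-12
        )

    def test_invariant_under_relabeling(self, rng):
        a = rng.integers(0, 3, size=40)
        b = rng.integers(0, 3, size=40)
        rename = {0: "alpha", 1: "beta", 2: "gamma"}
        r1 = cohens_kappa(a, b)
        r2 = cohens_kappa([rename[v] for v in a], [rename[v] for v in b])
        assert r1.kappa == pytest.approx(r2.kappa)


class TestPearson:
    def test_perfect_positive_negative(self):
        assert pearson_r([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)
        x = [0.0, 1.0, 2.0, 5.0]
        assert pearson_r(x, [-2 * v + 7 for v in x]) == pytest.approx(-1.0)

    def test_hand_computed(self):
        assert pearson_r([1, 2, 3], [1, 2, 4]) == pytest.approx(0.9820, abs=1e-4)

    def test_constant_input_undefined(self):
        assert pearson_r([1, 1, 1], [1, 2, 3]) is None

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2], [1, 2])


class TestBlandAltman:
    def test_identical_measurements(self):
        r = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.bias == 0 and r.lower_limit == 0 and r.upper_limit == 0

    def test_two_point_sample_sd(self):
        r = bland_altman([1.0, 0.0], [0.0, 1.0])  # differences (1, -1)
        assert r.bias == 0
        assert r.upper_limit == pytest.approx(1.96 * np.sqrt(2))
        assert r.lower_limit == pytest.approx(-1.96 * np.sqrt(2))

    def test_limits_symmetric_about_bias(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.2, size=30) + 0.5
        r = bland_altman(x, y)
        assert r.upper_limit - r.bias == pytest.approx(r.bias - r.lower_limit)

    def test_coverage_of_limits(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=5000)
        y = x + rng.normal(scale=0.3, size=5000)
        r = bland_altman(x, y)
        inside = np.mean(
            (r.differences >= r.lower_limit) & (r.differences <= r.upper_limit)
        )
        assert inside >= 0.94

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=20))
    def test_per_pair_outputs_consistent(self, xs):
        x = np.asarray(xs)
        y = x[::-1]
        r = bland_altman(x, y)
        np.testing.assert_allclose(r.differences, x - y)
        np.testing.assert_allclose(r.means, (x + y) / 2)
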