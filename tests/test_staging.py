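import math

import numpy as np
import pytest

from turstage.errors import (
    ConfigurationError,
    EmptySegmentationError,
    SingleClassError,
)
from turstage.staging import (
    FusionRule,
    TurRecord,
    classify,
    compute_tur,
    evaluate,
    fuse,
    gaussian_auc,
    mann_whitney_auc,
    roc_curve,
    simulate_tur_cohort,
)


def records(ia_scores, ib_scores):
    return ([TurRecord(f"ia{i}", "s", float(v), "IA") for i, v in enumerate(ia_scores)]
            + [TurRecord(f"ib{i}", "s", float(v), "IB") for i, v in enumerate(ib_scores)])


class TestComputeTur:
    def test_direct_arithmetic(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask.flat[:70] = 1
        mask.flat[70:100] = 2
        assert compute_tur(mask) == pytest.approx(0.30)

    def test_tumor_absent_zero(self):
        mask = np.full((4, 4), 1, dtype=np.uint8)
        assert compute_tur(mask) == 0.0

    def test_uterus_absent_one(self):
        mask = np.full((4, 4), 2, dtype=np.uint8)
        assert compute_tur(mask) == 1.0

    def test_empty_segmentation_raises(self):
        with pytest.raises(EmptySegmentationError, match="empty segmentation"):
            compute_tur(np.zeros((4, 4), dtype=np.uint8))


class TestRocCurve:
    def test_perfect_separation(self):
        r = roc_curve(records([0.1, 0.2], [0.5, 0.6]))
        assert r.auc == 1.0
        assert r.sens_at_criterion == 1.0 and r.spec_at_criterion == 1.0

    def test_all_identical_scores_half(self):
        r = roc_curve(records([0.3, 0.3], [0.3, 0.3]))
        assert r.auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            roc_curve(records([0.1, 0.2], []))

    def test_criterion_is_a_candidate_and_smallest_on_ties(self):
        # two thresholds reach the same Youden J; the smaller must win
        r = roc_curve(records([0.1, 0.3], [0.2, 0.4]))
        assert r.criterion in r.thresholds
        j = r.sensitivity + r.specificity - 1.0
        best = j.max()
        winners = r.thresholds[j == best]
        assert r.criterion == winners.min()

    def test_trapezoid_equals_mann_whitney_on_random_cohorts(self, rng):
        for _ in range(50):
            n1, n0 = rng.integers(1, 26), rng.integers(1, 26)
            ia = np.round(rng.random(n0), 1)   # rounding forces ties
            ib = np.round(rng.random(n1), 1)
            r = roc_curve(records(ia, ib))
            scores = np.concatenate([ia, ib])
            labels = np.concatenate([np.zeros(n0, bool), np.ones(n1, bool)])
            assert r.auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self, rng):
        ia, ib = rng.random(12) * 0.5, 0.2 + rng.random(9) * 0.5
        base = roc_curve(records(ia, ib)).auc
        warped = roc_curve(records(np.sqrt(ia), np.sqrt(ib))).auc
        assert warped == pytest.approx(base, abs=1e-12)

    def test_sensitivity_monotone_in_threshold(self, rng):
        r = roc_curve(records(rng.random(15), rng.random(10)))
        assert np.all(np.diff(r.sensitivity) <= 1e-12)
        assert np.all(np.diff(r.specificity) >= -1e-12)


class TestGaussianAuc:
    def test_equal_means_half(self):
        assert gaussian_auc(0.3, 0.1, 0.3, 0.2) == pytest.approx(0.5)

    def test_large_gap_approaches_one(self):
        assert gaussian_auc(0.0, 0.01, 1.0, 0.01) > 0.9999

    def test_sagittal_parameters(self):
        # Phi(0.231 / sqrt(0.077^2 + 0.125^2)) via the error function
        expect = 0.5 * (1 + math.erf(
            (0.334 - 0.103) / math.hypot(0.077, 0.125) / math.sqrt(2)))
        assert gaussian_auc(0.103, 0.077, 0.334, 0.125) == pytest.approx(expect)
        assert gaussian_auc(0.103, 0.077, 0.334, 0.125) == pytest.approx(0.942, abs=1e-3)

    def test_bad_sd(self):
        with pytest.raises(ConfigurationError):
            gaussian_auc(0.1, 0.0, 0.3, 0.1)

    def test_empirical_truncated_cohort_matches_closed_form(self):
        rng = np.random.default_rng(99)
        ia, ib = simulate_tur_cohort(0.103, 0.077, 0.334, 0.125,
                                     8000, 8000, rng, bounds=(0.02, 0.95))
        scores = np.concatenate([ia, ib])
        labels = np.concatenate([np.zeros(8000, bool), np.ones(8000, bool)])
        emp = mann_whitney_auc(scores, labels)
        assert abs(emp - gaussian_auc(0.103, 0.077, 0.334, 0.125)) <= 0.01


class TestClassify:
    def test_above_criterion_is_ib(self):
        assert classify(0.30, 0.198) == "IB"

    def test_exactly_at_criterion_is_ib(self):
        assert classify(0.198, 0.198) == "IB"

    def test_below_criterion_is_ia(self):
        assert classify(0.05, 0.198) == "IA"

    def test_bad_criterion(self):
        with pytest.raises(ConfigurationError):
            classify(0.5, 1.5)


class TestFuse:
    SEQS = ("axial_t2w", "axial_dwi", "sagittal_t2w")

    def test_one_vote_suffices_at_k1(self):
        votes = dict(zip(self.SEQS, ("IB", "IA", "IA")))
        assert fuse(votes, FusionRule(self.SEQS, 1)) == "IB"

    def test_two_votes_insufficient_at_k3(self):
        votes = dict(zip(self.SEQS, ("IB", "IB", "IA")))
        assert fuse(votes, FusionRule(self.SEQS, 3)) == "IA"

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_unanimity_always_ib(self, k):
        votes = dict(zip(self.SEQS, ("IB", "IB", "IB")))
        assert fuse(votes, FusionRule(self.SEQS, k)) == "IB"

    def test_missing_vote_names_sequence(self):
        with pytest.raises(ConfigurationError, match="sagittal_t2w"):
            fuse({"axial_t2w": "IB", "axial_dwi": "IA"}, FusionRule(self.SEQS, 2))

    def test_invalid_k(self):
        with pytest.raises(ConfigurationError):
            FusionRule(self.SEQS, 4)


class TestEvaluate:
    def test_clinical_operating_point_arithmetic(self):
        # 12/13 IB correct, 20/22 IA correct
        pred = ["IB"] * 12 + ["IA"] + ["IA"] * 20 + ["IB"] * 2
        true = ["IB"] * 13 + ["IA"] * 22
        perf = evaluate(pred, true)
        assert perf.accuracy == pytest.approx(32 / 35)
        assert perf.sensitivity == pytest.approx(12 / 13)
        assert perf.specificity == pytest.approx(20 / 22)

    def test_all_correct(self):
        perf = evaluate(["IA", "IB"], ["IA", "IB"])
        assert (perf.accuracy, perf.sensitivity, perf.specificity) == (1.0, 1.0, 1.0)

    def test_degenerate_all_ia(self):
        perf = evaluate(["IA", "IA", "IA"], ["IA", "IB", "IB"])
        assert perf.specificity == 1.0 and perf.sensitivity == 0.0

    def test_absent_class_gives_nan_not_zero(self):
        perf = evaluate(["IA", "IA"], ["IA", "IA"])
        assert math.isnan(perf.sensitivity) and perf.specificity == 1.0

    def test_accuracy_identity(self, rng):
        """accuracy == (sens*n_IB + spec*n_IA) / n, exactly."""
        for _ in range(20):
            n = int(rng.integers(4, 40))
            true = ["IB" if rng.random() < 0.4 else "IA" for _ in range(n)]
            if len(set(true)) < 2:
                continue
            pred = ["IB" if rng.random() < 0.5 else "IA" for _ in range(n)]
            perf = evaluate(pred, true)
            n_ib = true.count("IB")
            n_ia = true.count("IA")
            assert perf.accuracy == pytest.approx(
                (perf.sensitivity * n_ib + perf.specificity * n_ia) / n)
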