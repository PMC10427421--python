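import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dermrl.core import CLASS_ORDER, DiagnosisLabel, InvalidDistributionError, ManagementAction
from dermrl.metrics import (accuracy, average_recall, class_sensitivity, confusion,
                            entropy_comparison, operating_point,
                            paired_proportion_test, patient_metrics, proportion_ci,
                            roc_curve_points, auc, shannon_entropy)
from dermrl.policies import PolicyDecision
from dermrl.records import ClassifierState, LesionRecord, PatientCohort

D, A = DiagnosisLabel, ManagementAction

simplex7 = st.lists(st.floats(1e-6, 1.0), min_size=7, max_size=7).map(
    lambda w: np.array(w) / np.sum(w))


class TestConfusion:
    def test_toy_counts_and_row_normalization(self):
        cm = confusion([D.MEL, D.MEL, D.NV], [D.MEL, D.NV, D.NV])
        assert cm.counts[D.MEL.index, D.MEL.index] == 1
        row = cm.row_normalized[D.MEL.index]
        assert row[D.MEL.index] == pytest.approx(0.5)
        assert row[D.NV.index] == pytest.approx(0.5)
        assert class_sensitivity(cm, D.MEL) == pytest.approx(0.5)

    def test_nonempty_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        truth = [CLASS_ORDER[i] for i in rng.integers(0, 7, 200)]
        called = [CLASS_ORDER[i] for i in rng.integers(0, 7, 200)]
        cm = confusion(truth, called)
        sums = cm.row_normalized.sum(axis=1)
        assert np.allclose(sums[~np.isnan(sums)], 1.0)

    def test_perfect_predictions(self):
        truth = list(CLASS_ORDER) * 3
        cm = confusion(truth, truth)
        assert average_recall(cm) == 1.0
        assert accuracy(cm) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([D.MEL], [])

    def test_average_recall_invariant_to_class_duplication(self):
        truth = [D.MEL, D.MEL, D.NV, D.BCC]
        calls = [D.MEL, D.NV, D.NV, D.BCC]
        base = average_recall(confusion(truth, calls))
        dup = average_recall(confusion(truth + [D.NV] * 10, calls + [D.NV] * 10))
        assert dup == pytest.approx(base)


class TestEntropy:
    def test_known_values(self):
        one_hot = np.zeros(7); one_hot[3] = 1.0
        assert shannon_entropy(one_hot) == 0.0
        assert shannon_entropy(np.array([0.5, 0.5])) == pytest.approx(1.0)
        assert shannon_entropy(np.full(7, 1 / 7)) == pytest.approx(np.log2(7))

    @settings(deadline=None)
    @given(simplex7)
    def test_bounds_and_uniform_maximum(self, p):
        h = shannon_entropy(p)
        assert 0.0 <= h <= np.log2(7) + 1e-12
        if not np.allclose(p, 1 / 7):
            assert h < np.log2(7)

    def test_invalid_distribution(self):
        with pytest.raises(InvalidDistributionError):
            shannon_entropy(np.array([0.7, 0.7, -0.4]))


class TestEntropyComparison:
    def test_identical_sets_have_zero_median_delta(self):
        P = np.tile(np.full(7, 1 / 7), (10, 1))
        out = entropy_comparison(P, P)
        assert out["median_delta"] == 0.0
        assert out["p_value"] == 1.0

    def test_one_hot_versus_uniform_delta(self):
        A_ = np.tile(np.eye(7)[0], (10, 1))
        B = np.tile(np.full(7, 1 / 7), (10, 1))
        out = entropy_comparison(A_, B)
        assert out["median_delta"] == pytest.approx(np.log2(7))

    def test_flattened_copy_detected_by_wilcoxon(self):
        rng = np.random.default_rng(3)
        logits = rng.normal(scale=2.0, size=(200, 7))
        pa = np.exp(logits); pa /= pa.sum(1, keepdims=True)
        pb = np.exp(logits / 2); pb /= pb.sum(1, keepdims=True)  # flatter
        out = entropy_comparison(pa, pb)
        assert out["median_delta"] > 0
        assert out["p_value"] < 0.01

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            entropy_comparison(np.full((1, 7), 1 / 7), np.full((1, 7), 1 / 7))


class TestRoc:
    def test_endpoints(self):
        rng = np.random.default_rng(0)
        scores = rng.random(50)
        truth = rng.random(50) < 0.4
        fpr, tpr, cuts = roc_curve_points(scores, truth)
        assert (fpr[0], tpr[0]) == (1.0, 1.0)   # cut-off below all scores
        assert (fpr[-1], tpr[-1]) == (0.0, 0.0)  # cut-off at the max (strict >)
        assert np.all(np.diff(tpr) <= 1e-12) and np.all(np.diff(fpr) <= 1e-12)

    def test_null_scores_have_half_auc(self):
        rng = np.random.default_rng(1)
        scores = rng.random(10_000)
        truth = rng.random(10_000) < 0.5
        fpr, tpr, _ = roc_curve_points(scores, truth)
        assert auc(fpr, tpr) == pytest.approx(0.5, abs=0.02)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            roc_curve_points(np.array([0.1, 0.2]), np.array([True, True]))

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(2)
        scores = rng.random(500)
        truth = (scores + rng.normal(scale=0.3, size=500)) > 0.5
        if truth.all() or not truth.any():
            pytest.skip("degenerate draw")
        fpr, tpr, _ = roc_curve_points(scores, truth)
        # conventions differ at the cut-off (strict ">" here, ">=" in sklearn),
        # so agreement is close but not bit-exact
        assert auc(fpr, tpr) == pytest.approx(roc_auc_score(truth, scores), abs=1e-3)


class TestProportionStats:
    def test_wilson_interval_edges(self):
        lo, _ = proportion_ci(0, 20)
        assert lo == 0.0
        _, hi = proportion_ci(20, 20)
        assert hi == 1.0

    def test_wilson_symmetric_at_half(self):
        lo, hi = proportion_ci(50, 100)
        assert (0.5 - lo) == pytest.approx(hi - 0.5)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            proportion_ci(5, 4)

    def test_mcnemar_balanced_discordance(self):
        _, p = paired_proportion_test(5, 5)
        assert p == 1.0

    def test_mcnemar_one_sided_discordance_exact(self):
        _, p = paired_proportion_test(20, 0)
        assert p == pytest.approx(2 * 0.5**20, rel=1e-6)
        assert p < 0.001

    def test_mcnemar_chi2_branch_nonnegative(self):
        stat, p = paired_proportion_test(40, 20)
        assert stat >= 0 and 0 < p < 1

    def test_no_discordance_rejected(self):
        with pytest.raises(ValueError):
            paired_proportion_test(0, 0)


def _tiny_cohort():
    def rec(pid, i, label):
        p = np.full(7, 0.05); p[label.index] = 0.7
        return LesionRecord(f"{pid}-{i}", label,
                            ClassifierState(p, np.zeros(7), np.zeros(4)), pid)
    p1 = tuple(rec("p1", i, l) for i, l in enumerate([D.NV, D.NV, D.MEL]))
    p2 = tuple(rec("p2", i, l) for i, l in enumerate([D.NV, D.BKL]))
    return PatientCohort((("p1", p1), ("p2", p2)))


class TestPatientMetrics:
    def _decide(self, cohort, action):
        return [PolicyDecision(r.lesion_id, action, "fixed")
                for r in cohort.all_records()]

    def test_all_dismiss(self):
        cohort = _tiny_cohort()
        m = patient_metrics(cohort, self._decide(cohort, A.DISMISS))
        assert m["total_excised_benign"] == 0
        assert m["melanoma_actions"] == {"DISMISS": 1, "MONITOR": 0, "EXCISE": 0}

    def test_all_excise_counts_benign_per_patient(self):
        cohort = _tiny_cohort()
        m = patient_metrics(cohort, self._decide(cohort, A.EXCISE))
        assert m["excised_benign_per_patient"] == {"p1": 2, "p2": 2}

    def test_hand_tally(self):
        cohort = _tiny_cohort()
        by_action = {"p1-0": A.EXCISE, "p1-1": A.MONITOR, "p1-2": A.EXCISE,
                     "p2-0": A.DISMISS, "p2-1": A.MONITOR}
        dec = [PolicyDecision(r.lesion_id, by_action[r.lesion_id], "hand")
               for r in cohort.all_records()]
        m = patient_metrics(cohort, dec)
        assert m["excised_benign_per_patient"] == {"p1": 1, "p2": 0}
        assert m["monitored_benign"] == 2
        assert m["melanoma_actions"]["EXCISE"] == 1
        # conservation: every lesion is counted exactly once over the actions
        assert sum(m["action_totals"].values()) == cohort.n_lesions

    def test_missing_decision_rejected(self):
        cohort = _tiny_cohort()
        dec = self._decide(cohort, A.DISMISS)[:-1]
        with pytest.raises(ValueError, match="no decision"):
            patient_metrics(cohort, dec)


class TestOperatingPoint:
    def test_matches_manual_rates(self):
        truth = [D.MEL, D.BCC, D.NV, D.NV]
        dec = [PolicyDecision(str(i), a, "t") for i, a in
               enumerate([A.EXCISE, A.DISMISS, A.EXCISE, A.DISMISS])]
        op = operating_point(dec, truth)
        assert op.tpr == pytest.approx(0.5)
        assert op.fpr == pytest.approx(0.5)
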