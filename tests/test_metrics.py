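import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octseg.metrics import (FoldAssignment, aggregate_reports, confusion_counts,
                            crossval_folds, evaluate_masks, metrics_report,
                            roc_auc)


def _rank_statistic_auc(scores, truth):
    """Brute-force pairwise oracle: P(s_pos > s_neg) + 0.5 P(tie)."""
    pos = scores[truth > 0]
    neg = scores[truth == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestConfusionCounts:
    def test_perfect_prediction(self):
        truth = np.zeros((10, 10), int)
        truth[:2, :4] = 1
        assert confusion_counts(truth, truth) == (8, 0, 0, 92)

    def test_total_disagreement(self):
        truth = np.zeros((10, 10), int)
        truth[0] = 1
        tp, fp, fn, tn = confusion_counts(1 - truth, truth)
        assert tp == 0 and tn == 0

    def test_hand_constructed_counts(self):
        truth = np.zeros((10, 10), int)
        pred = np.zeros((10, 10), int)
        truth.ravel()[:10] = 1
        pred.ravel()[2:12] = 1   # overlap 8, 2 extra, 2 missed
        assert confusion_counts(pred, truth) == (8, 2, 2, 88)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_counts(np.zeros((3, 3)), np.zeros((4, 4)))


class TestMetricsReport:
    def test_worked_example(self):
        rep = metrics_report(8, 2, 2, 88)
        assert rep.precision == pytest.approx(0.8)
        assert rep.sensitivity == pytest.approx(0.8)
        assert rep.specificity == pytest.approx(88 / 90)
        assert rep.f1 == pytest.approx(0.8)

    def test_perfect_prediction_all_ones(self):
        rep = metrics_report(50, 0, 0, 50)
        assert (rep.precision, rep.sensitivity, rep.specificity, rep.f1) == \
            (1.0, 1.0, 1.0, 1.0)

    def test_zero_tp_zeroes_metrics(self):
        rep = metrics_report(0, 3, 3, 94)
        assert rep.precision == 0 and rep.sensitivity == 0 and rep.f1 == 0

    def test_zero_denominator_warns_not_raises(self):
        with pytest.warns(RuntimeWarning, match="precision"):
            rep = metrics_report(0, 0, 3, 97)  # nothing predicted positive
        assert rep.precision == 0.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics_report(0, 0, 0, 0)

    def test_f1_is_harmonic_mean_of_precision_sensitivity(self):
        rep = metrics_report(30, 10, 20, 40)
        hmean = 2 / (1 / rep.precision + 1 / rep.sensitivity)
        assert rep.f1 == pytest.approx(hmean)

    def test_counts_partition_total(self):
        pred = np.eye(8, dtype=int)
        truth = np.ones((8, 8), int)
        assert sum(confusion_counts(pred, truth)) == 64


class TestROCAUC:
    def test_perfect_classifier(self):
        truth = np.array([0, 0, 1, 1, 0, 1])
        assert roc_auc(truth.astype(float), truth).auc == pytest.approx(1.0)

    def test_reversed_classifier(self):
        truth = np.array([0, 0, 1, 1, 0, 1])
        assert roc_auc(1.0 - truth, truth).auc == pytest.approx(0.0)

    def test_chance_level_large_sample(self):
        rng = np.random.default_rng(42)
        truth = rng.integers(0, 2, 100_000)
        scores = rng.random(100_000)  # independent of labels
        assert roc_auc(scores, truth).auc == pytest.approx(0.5, abs=0.01)

    def test_matches_rank_statistic_oracle(self, rng):
        for _ in range(5):
            truth = rng.integers(0, 2, 400)
            truth[0], truth[1] = 0, 1
            scores = np.round(rng.random(400), 2)  # coarse grid forces ties
            assert roc_auc(scores, truth).auc == pytest.approx(
                _rank_statistic_auc(scores, truth), abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_score_negation_antisymmetry(self, seed):
        r = np.random.default_rng(seed)
        truth = r.integers(0, 2, 50)
        truth[:2] = [0, 1]
        scores = r.random(50)
        a = roc_auc(scores, truth).auc
        b = roc_auc(-scores, truth).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))


class TestAggregation:
    def test_mean_sd_matches_recomputation(self):
        reports = [metrics_report(8, 2, 2, 88), metrics_report(5, 5, 0, 90),
                   metrics_report(10, 0, 5, 85)]
        agg = aggregate_reports(reports)
        f1s = np.array([r.f1 for r in reports])
        assert agg["f1"]["mean"] == pytest.approx(f1s.mean())
        assert agg["f1"]["sd"] == pytest.approx(f1s.std())

    def test_pooled_mode_sums_counts(self):
        reports = [metrics_report(8, 2, 2, 88), metrics_report(4, 1, 1, 94)]
        agg = aggregate_reports(reports, mode="pooled")
        assert agg["tp"] == 12 and agg["tn"] == 182


class TestCrossvalFolds:
    @staticmethod
    def entries(n_patients, scans=2):
        return [{"patient_id": f"P{p:03d}", "scan": s}
                for p in range(n_patients) for s in range(scans)]

    def test_even_patient_split(self):
        folds = crossval_folds(self.entries(10), k=5, seed=0)
        assert len(folds.folds) == 5
        assert all(len(f) == 2 for f in folds.folds)

    def test_test_folds_partition_samples(self):
        entries = self.entries(7, scans=3)
        folds = crossval_folds(entries, k=3, seed=1)
        seen = []
        for i in range(3):
            seen += [tuple(e.items()) for e in folds.test_entries(entries, i)]
        assert len(seen) == len(entries) and len(set(seen)) == len(entries)

    def test_no_patient_spans_folds(self):
        entries = self.entries(9, scans=4)
        folds = crossval_folds(entries, k=4, seed=3)
        for i in range(4):
            test_p = {e["patient_id"] for e in folds.test_entries(entries, i)}
            train_p = {e["patient_id"] for e in folds.train_entries(entries, i)}
            assert not (test_p & train_p)

    def test_deterministic_given_seed(self):
        a = crossval_folds(self.entries(10), 5, seed=9)
        b = crossval_folds(self.entries(10), 5, seed=9)
        assert a.folds == b.folds

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError, match="patients"):
            crossval_folds(self.entries(3), k=5, seed=0)
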