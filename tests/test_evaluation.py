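"""Subject-wise evaluation: split hygiene, majority vote against a counting
oracle, metrics, rank-based AUC against the pairwise oracle, fold repetition
with a stub model, and the assessment-week sensitivity test."""

import numpy as np
import pytest

from eegmark.evaluation import (SplitPlan, aggregate_subjects, make_split,
                                metrics, roc_auc, run_folds,
                                timepoint_sensitivity)
from eegmark.preprocess import SegmentSet


def make_cohort_meta(n_per_class=30, segs_per_subject=10, seed=0):
    rng = np.random.default_rng(seed)
    ids, labels, counts = [], [], []
    for cls in (0, 1):
        for i in range(n_per_class):
            ids.append(f"c{cls}_s{i}")
            labels.append(cls)
            counts.append(segs_per_subject + int(rng.integers(0, 5)))
    return np.array(ids), np.array(labels), np.array(counts)


class TestMakeSplit:
    def test_diagnosis_test_set_balanced_20_20(self):
        ids, labels, counts = make_cohort_meta(30)
        plan = make_split(ids, labels, counts, "diagnosis", seed=1)
        test_labels = [labels[list(ids).index(s)] for s in plan.test_subjects]
        assert len(plan.test_subjects) == 40
        assert sum(test_labels) == 20

    def test_response_test_set_balanced_10_10(self):
        ids, labels, counts = make_cohort_meta(15)
        plan = make_split(ids, labels, counts, "response", seed=2)
        test_labels = [labels[list(ids).index(s)] for s in plan.test_subjects]
        assert len(plan.test_subjects) == 20
        assert sum(test_labels) == 10

    def test_sets_disjoint_and_exhaustive(self):
        ids, labels, counts = make_cohort_meta(25)
        plan = make_split(ids, labels, counts, "diagnosis", seed=3)
        a, b, c = (set(plan.train_subjects), set(plan.val_subjects),
                   set(plan.test_subjects))
        assert not (a & b or a & c or b & c)
        assert a | b | c == set(ids)

    def test_validation_covers_five_percent_of_segments(self):
        ids, labels, counts = make_cohort_meta(40, segs_per_subject=50)
        plan = make_split(ids, labels, counts, "diagnosis", seed=4)
        seg_of = dict(zip(ids, counts))
        val_segs = sum(seg_of[s] for s in plan.val_subjects)
        rest = sum(seg_of[s] for s in ids if s not in set(plan.test_subjects))
        assert val_segs >= 0.05 * rest

    def test_deterministic_given_seed(self):
        ids, labels, counts = make_cohort_meta(30)
        p1 = make_split(ids, labels, counts, "diagnosis", seed=7)
        p2 = make_split(ids, labels, counts, "diagnosis", seed=7)
        assert p1 == p2

    def test_insufficient_cohort_rejected(self):
        ids, labels, counts = make_cohort_meta(10)
        with pytest.raises(ValueError):
            make_split(ids, labels, counts, "diagnosis", seed=0)

    def test_overlapping_plan_rejected(self):
        with pytest.raises(ValueError):
            SplitPlan(("a", "b"), ("b",), ("c",), "diagnosis", 0)


class TestAggregation:
    def test_majority_positive(self):
        probs = np.array([0.9] * 6 + [0.1] * 4)
        ids = np.array(["s"] * 10)
        labels = np.ones(10, dtype=int)
        (pred,) = aggregate_subjects(probs, ids, labels)
        assert pred.predicted_label == 1
        assert pred.positive_fraction == 0.6

    def test_exact_tie_resolves_positive(self):
        """'50% or more' counts as the positive label."""
        probs = np.array([0.9] * 5 + [0.1] * 5)
        (pred,) = aggregate_subjects(probs, np.array(["s"] * 10),
                                     np.zeros(10, dtype=int))
        assert pred.predicted_label == 1

    def test_matches_brute_force_counting_oracle(self):
        rng = np.random.default_rng(11)
        n_subjects = 50
        ids = np.repeat([f"s{i}" for i in range(n_subjects)],
                        rng.integers(1, 20, n_subjects))
        probs = rng.random(len(ids))
        subj_label = {f"s{i}": int(l) for i, l in enumerate(
            rng.integers(0, 2, n_subjects))}
        labels = np.array([subj_label[s] for s in ids])
        preds = aggregate_subjects(probs, ids, labels)
        for p in preds:
            mask = ids == p.subject_id
            n_pos = sum(1 for v in probs[mask] if v >= 0.5)  # direct count
            assert p.n_segments == mask.sum()
            assert p.positive_fraction == n_pos / mask.sum()
            assert p.predicted_label == int(2 * n_pos >= mask.sum())


class TestMetrics:
    def test_twenty_patient_example(self):
        """tp=9 fn=3 tn=7 fp=1: sens 75%, spec 87.5%, acc 80%."""
        from eegmark.evaluation import SubjectPrediction

        preds = (
            [SubjectPrediction(f"tp{i}", 1.0, 1, 1, 5) for i in range(9)]
            + [SubjectPrediction(f"fn{i}", 0.0, 0, 1, 5) for i in range(3)]
            + [SubjectPrediction(f"tn{i}", 0.0, 0, 0, 5) for i in range(7)]
            + [SubjectPrediction("fp0", 1.0, 1, 0, 5)]
        )
        cm, m = metrics(preds)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (9, 3, 7, 1)
        assert m["sensitivity"] == 0.75
        assert m["specificity"] == 0.875
        assert m["accuracy"] == 0.80

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            metrics([])


class TestRocAuc:
    @staticmethod
    def preds_from(scores, labels):
        from eegmark.evaluation import SubjectPrediction

        return [SubjectPrediction(f"s{i}", s, int(s >= 0.5), l, 1)
                for i, (s, l) in enumerate(zip(scores, labels))]

    def test_perfect_separation(self):
        preds = self.preds_from([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc_auc(preds) == 1.0

    def test_identical_scores(self):
        preds = self.preds_from([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert roc_auc(preds) == 0.5

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(13)
        scores = rng.random(20)
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]  # both classes present
        preds = self.preds_from(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        oracle = np.mean([(1.0 if p > n else 0.5 if p == n else 0.0)
                          for p in pos for n in neg])
        assert roc_auc(preds) == pytest.approx(oracle, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(self.preds_from([0.4, 0.6], [1, 1]))


def stub_train_fn(separation=4.0):
    """Stub 'model': score each segment by its mean amplitude (the fixture
    encodes the label there), bypassing CNN training."""

    def factory(train_segs, val_segs, seed):
        def predict(segs):
            m = segs.data.mean(axis=(1, 2))
            return 1.0 / (1.0 + np.exp(-separation * m))
        return predict

    return factory


def stub_segments(n_per_class=25, segs_per_subject=6, shift=1.0, seed=0):
    rng = np.random.default_rng(seed)
    data, ids, labels = [], [], []
    for cls in (0, 1):
        for i in range(n_per_class):
            for _ in range(segs_per_subject):
                x = rng.normal(size=(10, 500)) + (shift if cls else -shift)
                data.append(x)
                ids.append(f"c{cls}_s{i}")
                labels.append(cls)
    return SegmentSet(np.array(data), np.array(ids, dtype=object),
                      np.array(labels))


class TestRunFolds:
    def test_two_folds_with_stub_model(self):
        segs = stub_segments()
        report = run_folds(segs, "diagnosis", k=2, base_seed=5,
                           train_fn=stub_train_fn())
        assert len(report.subject_accuracies) == 2
        assert report.mean_subject_accuracy == pytest.approx(
            np.mean(report.subject_accuracies))
        assert report.best_fold == max(report.subject_accuracies)
        # the stub reads the planted shift, so accuracy is high
        assert report.mean_subject_accuracy >= 0.9

    def test_fold_assignment_deterministic(self):
        segs = stub_segments()
        r1 = run_folds(segs, "diagnosis", k=2, base_seed=8,
                       train_fn=stub_train_fn())
        r2 = run_folds(segs, "diagnosis", k=2, base_seed=8,
                       train_fn=stub_train_fn())
        assert r1.subject_accuracies == r2.subject_accuracies

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            run_folds(stub_segments(), "diagnosis", k=1, base_seed=0)


class TestTimepointSensitivity:
    def test_identical_distributions_give_zero_t(self):
        t, p = timepoint_sensitivity([1, 0, 1, 0], [0, 1, 0, 1])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_fully_separated_groups(self):
        t, p = timepoint_sensitivity([1, 1, 1, 1], [0, 0, 0, 0])
        assert abs(t) == np.inf or abs(t) > 10
        assert p < 0.01

    def test_matches_welch_formula(self):
        a = np.array([1.0, 1.0, 0.0, 1.0, 0.0])
        b = np.array([0.0, 1.0, 0.0, 0.0])
        t, _ = timepoint_sensitivity(a, b)
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert t == pytest.approx((a.mean() - b.mean()) / se, rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            timepoint_sensitivity([], [1, 0])
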