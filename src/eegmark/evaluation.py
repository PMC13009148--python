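"""Leakage-safe splits and subject-wise majority-vote evaluation.

The unit of evaluation is the subject, not the 2-s segment: a subject is
predicted positive when at least 50% of their segments are classified
positive (ties resolve to the positive class).  Test sets are balanced whole
subjects never seen in training or validation (20/20 for diagnosis, 10/10
for response); validation takes roughly 5% of the remaining segments in
whole-subject blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from eegmark.preprocess import SegmentSet, normalize_amplitude
from eegmark.cnn import (
    ModelSpec, TrainConfig, build_model, predict_segments, train,
)

__all__ = [
    "SplitPlan", "SubjectPrediction", "ConfusionMatrix", "FoldReport",
    "task_labeller", "make_split", "aggregate_subjects", "metrics",
    "roc_auc", "run_folds", "timepoint_sensitivity", "train_and_score",
]

TEST_PER_CLASS = {"diagnosis": 20, "response": 10}


@dataclass(frozen=True)
class SplitPlan:
    train_subjects: tuple[str, ...]
    val_subjects: tuple[str, ...]
    test_subjects: tuple[str, ...]
    task: str
    seed: int

    def __post_init__(self) -> None:
        a, b, c = map(set, (self.train_subjects, self.val_subjects,
                            self.test_subjects))
        if a & b or a & c or b & c:
            raise ValueError("train/val/test subject sets must be disjoint")


@dataclass(frozen=True)
class SubjectPrediction:
    subject_id: str
    positive_fraction: float
    predicted_label: int
    true_label: int
    n_segments: int


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class FoldReport:
    subject_accuracies: list[float]
    segment_accuracies: list[float]
    sensitivities: list[float]
    specificities: list[float]
    aucs: list[float]
    per_subject_correct_sd: list[float]

    @property
    def mean_subject_accuracy(self) -> float:
        return float(np.mean(self.subject_accuracies))

    @property
    def sd_subject_accuracy(self) -> float:
        return float(np.std(self.subject_accuracies, ddof=1))

    @property
    def best_fold(self) -> float:
        return float(np.max(self.subject_accuracies))


def task_labeller(task: str):
    """Map a subject record to its binary task label (None = not in task)."""
    if task == "diagnosis":
        return lambda r: 1 if r.group == "MDD" else 0
    if task == "response":
        return lambda r: (None if r.responder == "NA"
                          else (1 if r.responder == "R" else 0))
    raise ValueError(f"unknown task {task!r}")


def make_split(subject_ids, labels, n_segments, task: str, seed: int,
               val_fraction: float = 0.05) -> SplitPlan:
    """Draw a balanced held-out test set, then a ~5% whole-subject validation set.

    ``subject_ids``, ``labels`` and ``n_segments`` are aligned per-subject
    arrays.  Test subjects are drawn at random per class (20 per class for
    diagnosis, 10 for response); validation accumulates whole subjects until
    at least ``val_fraction`` of the remaining segments is covered.
    """
    subject_ids = np.asarray(subject_ids)
    labels = np.asarray(labels)
    n_segments = np.asarray(n_segments)
    per_class = TEST_PER_CLASS[task]
    rng = np.random.default_rng(seed)
    test = []
    for cls in (0, 1):
        pool = subject_ids[labels == cls]
        if len(pool) < per_class + 1:
            raise ValueError(
                f"class {cls} has {len(pool)} subjects; need > {per_class}")
        test.extend(rng.choice(pool, size=per_class, replace=False))
    test_set = set(test)
    rest_mask = np.array([s not in test_set for s in subject_ids])
    rest_ids = subject_ids[rest_mask]
    rest_labels = labels[rest_mask]
    rest_segs = n_segments[rest_mask]
    # whole-subject validation, alternating classes so both are represented
    per_class_order = {
        cls: iter(rng.permutation(np.flatnonzero(rest_labels == cls)))
        for cls in (0, 1)
    }
    seg_of = dict(zip(range(len(rest_ids)), rest_segs))
    needed = val_fraction * rest_segs.sum()
    val, got, cls = [], 0, 0
    while got < needed:
        try:
            i = next(per_class_order[cls])
        except StopIteration:
            i = next(per_class_order[1 - cls])
        val.append(rest_ids[i])
        got += seg_of[i]
        cls = 1 - cls
    val_set = set(val)
    train = [s for s in rest_ids if s not in val_set]
    return SplitPlan(tuple(train), tuple(val), tuple(test), task, seed)


def aggregate_subjects(segment_probs: np.ndarray, subject_ids: np.ndarray,
                       true_labels: np.ndarray, threshold: float = 0.5,
                       vote: float = 0.5) -> list[SubjectPrediction]:
    """Majority vote: subject positive iff >= ``vote`` of segments are positive."""
    segment_probs = np.asarray(segment_probs)
    subject_ids = np.asarray(subject_ids)
    true_labels = np.asarray(true_labels)
    preds = []
    for sid in np.unique(subject_ids):
        mask = subject_ids == sid
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"subject {sid} has no surviving segments; excluded")
            continue
        frac = float((segment_probs[mask] >= threshold).mean())
        lab = int(np.unique(true_labels[mask])[0])
        preds.append(SubjectPrediction(
            subject_id=str(sid), positive_fraction=frac,
            predicted_label=int(frac >= vote), true_label=lab, n_segments=n))
    return preds


def metrics(preds: list[SubjectPrediction]
            ) -> tuple[ConfusionMatrix, dict[str, float]]:
    """Confusion matrix plus accuracy / sensitivity / specificity."""
    if not preds:
        raise ValueError("no subject predictions")
    tp = sum(p.predicted_label == 1 and p.true_label == 1 for p in preds)
    fp = sum(p.predicted_label == 1 and p.true_label == 0 for p in preds)
    tn = sum(p.predicted_label == 0 and p.true_label == 0 for p in preds)
    fn = sum(p.predicted_label == 0 and p.true_label == 1 for p in preds)
    cm = ConfusionMatrix(tp, fp, tn, fn)
    out = {"accuracy": (tp + tn) / cm.total}
    out["sensitivity"] = tp / (tp + fn) if tp + fn else float("nan")
    out["specificity"] = tn / (tn + fp) if tn + fp else float("nan")
    return cm, out


def roc_auc(preds: list[SubjectPrediction]) -> float:
    """AUC by the rank (Mann-Whitney) statistic over subject-level scores."""
    scores = np.array([p.positive_fraction for p in preds])
    labels = np.array([p.true_label for p in preds])
    n1, n0 = int((labels == 1).sum()), int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _segment_counts(segs: SegmentSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sids, idx, counts = np.unique(segs.subject_ids, return_index=True,
                                  return_counts=True)
    labels = segs.labels[idx]
    return sids, labels, counts


def train_and_score(segs: SegmentSet, plan: SplitPlan,
                    spec: ModelSpec, cfg: TrainConfig,
                    train_fn=None) -> dict:
    """Train on a split and evaluate subject-wise on its held-out test set.

    ``train_fn(train_segs, val_segs, seed) -> callable(segs)->probs`` may
    replace the CNN (stub models in tests); default builds and trains the
    convolutional classifier.
    """
    tr = segs.for_subjects(plan.train_subjects)
    va = segs.for_subjects(plan.val_subjects)
    te = segs.for_subjects(plan.test_subjects)
    tr, stats_ = normalize_amplitude(tr)
    va, _ = normalize_amplitude(va, stats_)
    te, _ = normalize_amplitude(te, stats_)
    if train_fn is None:
        model = build_model(spec, seed=cfg.seed)
        model.norm_stats = stats_
        model = train(model, tr, va, cfg)
        predict = lambda s: predict_segments(model, s)
    else:
        predict = train_fn(tr, va, cfg.seed)
        model = None
    probs = predict(te)
    seg_acc = float(((probs >= 0.5).astype(int) == te.labels).mean())
    preds = aggregate_subjects(probs, te.subject_ids, te.labels)
    cm, m = metrics(preds)
    correct = np.array([p.predicted_label == p.true_label for p in preds], float)
    return {
        "model": model,
        "subject_predictions": preds,
        "confusion": cm,
        "subject_accuracy": m["accuracy"],
        "segment_accuracy": seg_acc,
        "sensitivity": m["sensitivity"],
        "specificity": m["specificity"],
        "auc": roc_auc(preds),
        "per_subject_correct_sd": float(correct.std(ddof=1)) if len(correct) > 1
        else 0.0,
    }


def run_folds(segs: SegmentSet, task: str, k: int = 5, base_seed: int = 0,
              spec: ModelSpec = ModelSpec(), cfg: TrainConfig = TrainConfig(),
              train_fn=None) -> FoldReport:
    """Repeat split -> train -> subject-wise scoring over ``k`` random folds."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    sids, labels, counts = _segment_counts(segs)
    report = FoldReport([], [], [], [], [], [])
    for fold in range(k):
        fold_seed = int(np.random.SeedSequence([base_seed, fold])
                        .generate_state(1)[0] % (2**31))
        plan = make_split(sids, labels, counts, task, fold_seed)
        res = train_and_score(segs, plan, spec,
                              replace(cfg, seed=fold_seed), train_fn)
        report.subject_accuracies.append(res["subject_accuracy"])
        report.segment_accuracies.append(res["segment_accuracy"])
        report.sensitivities.append(res["sensitivity"])
        report.specificities.append(res["specificity"])
        report.aucs.append(res["auc"])
        report.per_subject_correct_sd.append(res["per_subject_correct_sd"])
    return report


def timepoint_sensitivity(correct_a, correct_b) -> tuple[float, float]:
    """Welch two-sample t-test on per-subject correctness between week groups."""
    a = np.asarray(correct_a, dtype=float)
    b = np.asarray(correct_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both assessment-week groups must be non-empty")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # degenerate variances: identical means carry no evidence, separated
        # means are infinitely strong
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
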