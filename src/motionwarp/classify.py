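"""Minimum-warping-cost labeling and k-fold evaluation.

A query sequence is assigned the label of the template with the smallest
total warping cost — direct template matching, no training phase.  The
module also provides the evaluation harness used to compare the direct DTW
matcher against the two equalizer + back-propagation-network pipelines under
stratified k-fold cross-validation (k = 5 by convention, so 130 samples
give folds of 26).

:class:`DTWTemplateClassifier` wraps template construction plus matching as
a scikit-learn estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .ann import BackpropClassifier
from .dtw import dtw_cost
from .equalize import equalize, normalize_unit_interval
from .sequence import MotionSequence
from .templates import TemplateSet, build_averaged_mpps, select_random_mpps

__all__ = ["EvaluationReport", "classify_sequence", "kfold_split",
           "kfold_evaluate", "DTWTemplateClassifier"]


@dataclass
class EvaluationReport:
    """Per-fold correctness counts and accuracies of a k-fold run.

    ``per_fold`` rows are (correct_count, error_count, accuracy_percent);
    ``average_accuracy`` is the mean of the per-fold accuracies, in percent,
    reported to two decimals by :meth:`to_frame`.
    """

    method: str
    fold_assignments: dict
    per_fold: list
    average_accuracy: float
    seed: object = None

    def to_frame(self) -> pd.DataFrame:
        k = len(self.per_fold)
        rows = []
        for v, (c, e, acc) in enumerate(self.per_fold, start=1):
            training = ", ".join(f"#{f}" for f in range(1, k + 1) if f != v)
            rows.append({"training_folds": training, "validation_fold": f"#{v}",
                         "correct": c, "error": e,
                         "accuracy_pct": round(acc, 2)})
        rows.append({"training_folds": "Average", "validation_fold": "",
                     "correct": round(np.mean([r[0] for r in self.per_fold]), 2),
                     "error": round(np.mean([r[1] for r in self.per_fold]), 2),
                     "accuracy_pct": round(self.average_accuracy, 2)})
        frame = pd.DataFrame(rows)
        # keep integer fold counts displayable next to the fractional average
        for col in ("correct", "error"):
            frame[col] = [int(v) if float(v).is_integer() else v
                          for v in frame[col]]
        return frame


def classify_sequence(z, template_set: TemplateSet):
    """Label of the template with minimum total warping cost to ``z``.

    Ties are broken toward the lowest category code.  The query is matched
    as given; any normalization happens upstream so that an exact copy of a
    template always matches it at zero cost.
    """
    if not template_set.templates:
        raise ValueError("empty template set")
    best_label, best_cost = None, np.inf
    for label in sorted(template_set.templates, key=lambda l: (str(type(l)), l)):
        cost = dtw_cost(z, template_set.templates[label])
        if cost < best_cost:
            best_label, best_cost = label, cost
    return best_label


def kfold_split(labels, k: int, seed=None) -> np.ndarray:
    """Stratified fold assignment (values in 1..k) for a label vector.

    Folds are disjoint, cover all samples, and differ in size by at most
    one; within each class the members are shuffled then dealt cyclically,
    with the dealing position carried across classes so the overall sizes
    stay balanced.  Deterministic under ``seed``.
    """
    labels = np.asarray(labels)
    n = labels.size
    k = int(k)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k = {k} exceeds the sample count {n}")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    cursor = 0
    for cls in sorted(np.unique(labels).tolist(), key=str):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for i in idx:
            folds[i] = cursor % k + 1
            cursor += 1
    return folds


def _check_training_classes(train_labels, all_labels, fold):
    missing = set(all_labels) - set(train_labels)
    if missing:
        raise ValueError(
            f"class(es) {sorted(missing, key=str)} absent from the training "
            f"union of fold {fold}; add samples or lower k")


def kfold_evaluate(samples, k=5, method="dtw", seed=None,
                   target_length=None, ann_params=None) -> EvaluationReport:
    """Stratified k-fold cross-validation of one recognition method.

    Parameters
    ----------
    samples : list of MotionSequence (labeled)
    k : int, default 5
    method : {'dtw', 'ann_dft', 'ann_conv'}
        'dtw' builds averaged templates on the training folds and labels the
        held-out fold by minimum warping cost; the 'ann_*' variants equalize
        every sequence to a common length with the named preprocessor and
        train the back-propagation network on the training folds.
    seed : int, optional
        Controls the fold shuffle and network initialization.
    target_length : int, optional
        Common equalized length M; defaults to the longest sequence in the
        dataset (the equalizers only upsample).
    ann_params : dict, optional
        Extra keyword arguments for :class:`BackpropClassifier`.
    """
    samples = list(samples)
    labels = np.array([s.label for s in samples], dtype=object)
    classes = sorted(set(labels.tolist()), key=str)
    if method not in ("dtw", "ann_dft", "ann_conv"):
        raise ValueError(f"unknown evaluation method {method!r}")
    folds = kfold_split(labels, k, seed=seed)
    if target_length is None:
        target_length = max(len(s) for s in samples)

    eq_method = {"ann_dft": "dft", "ann_conv": "conv"}.get(method)
    if eq_method is not None:
        X_eq = np.vstack([equalize(s.samples, target_length, method=eq_method)
                          for s in samples])

    per_fold = []
    for v in range(1, k + 1):
        test_idx = np.flatnonzero(folds == v)
        train_idx = np.flatnonzero(folds != v)
        _check_training_classes(labels[train_idx], classes, v)
        if method == "dtw":
            tset = build_averaged_mpps([samples[i] for i in train_idx],
                                       target_length=target_length)
            preds = [classify_sequence(normalize_unit_interval(samples[i].samples),
                                       tset) for i in test_idx]
        else:
            clf = BackpropClassifier(random_state=seed,
                                     **(ann_params or {}))
            clf.fit(X_eq[train_idx], labels[train_idx])
            preds = clf.predict(X_eq[test_idx]).tolist()
        correct = int(sum(p == labels[i] for p, i in zip(preds, test_idx)))
        error = len(test_idx) - correct
        per_fold.append((correct, error, 100.0 * correct / len(test_idx)))

    avg = float(np.mean([acc for _, _, acc in per_fold]))
    assignments = {i: int(f) for i, f in enumerate(folds)}
    return EvaluationReport(method=method, fold_assignments=assignments,
                            per_fold=per_fold, average_accuracy=avg, seed=seed)


class DTWTemplateClassifier(ClassifierMixin, BaseEstimator):
    """Nearest-template classifier under total warping cost.

    ``fit`` builds one matching pattern paradigm per class from the labeled
    training sequences (averaged after equalization + normalization, or a
    raw random pick); ``predict`` labels each query by the template of
    minimum total warping cost.

    Parameters
    ----------
    policy : {'averaged', 'random'}, default 'averaged'
    equalizer : {'dft', 'conv'}, default 'dft'
        Preprocessor used to bring training samples to a common length
        before averaging (ignored for ``policy='random'``).
    target_length : int, optional
        Template length M; None means the longest training sequence.
    normalize : bool, default True
        Min-max normalize training samples before averaging and queries
        before matching (skipped for raw random templates).
    reject_outliers : bool, default False
        Drop per-class cost outliers and re-average once.
    random_state : int, optional
        Seed for the random-selection policy.
    """

    def __init__(self, policy="averaged", equalizer="dft", target_length=None,
                 normalize=True, reject_outliers=False, random_state=None):
        self.policy = policy
        self.equalizer = equalizer
        self.target_length = target_length
        self.normalize = normalize
        self.reject_outliers = reject_outliers
        self.random_state = random_state

    @staticmethod
    def _sequences(X, y):
        return [MotionSequence(np.asarray(x, dtype=float), label=lab)
                for x, lab in zip(X, y)]

    def fit(self, X, y):
        seqs = self._sequences(X, np.asarray(y, dtype=object))
        if self.policy == "averaged":
            self.templates_ = build_averaged_mpps(
                seqs, target_length=self.target_length, method=self.equalizer,
                normalize=self.normalize, reject_outliers=self.reject_outliers)
        elif self.policy == "random":
            self.templates_ = select_random_mpps(seqs, seed=self.random_state)
        else:
            raise ValueError(f"unknown template policy {self.policy!r}")
        self.classes_ = np.array(self.templates_.labels, dtype=object)
        return self

    def _prepare_query(self, x):
        q = np.asarray(x, dtype=float).ravel()
        if self.normalize and self.templates_.method.startswith("averaged"):
            q = normalize_unit_interval(q)
        return q

    def decision_function(self, X):
        """Matrix of total warping costs, one row per query, one column per
        class (in ``classes_`` order); lower is more similar."""
        if not hasattr(self, "templates_"):
            raise AttributeError("classifier is not fitted")
        rows = []
        for x in X:
            q = self._prepare_query(x)
            rows.append([dtw_cost(q, self.templates_.templates[c])
                         for c in self.classes_])
        return np.asarray(rows)

    def predict(self, X):
        costs = self.decision_function(X)
        return self.classes_[np.argmin(costs, axis=1)]
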