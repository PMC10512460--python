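"""Cross-validation, cross-dataset transfer, and significance testing.

Leave-one-subject-out cross-validation (LOOCV) refits the entire
pipeline — edge selection included — with each subject held out, so no
information from the held-out subject reaches the model.  For speed the
per-fold edge-label correlations are computed by downdating cohort-level
sufficient statistics (sums, squared sums, label cross-products), which
is algebraically identical to correlating within the fold from scratch;
a fold's fitted model is the same object :func:`cpmsvm.cpm.fit_cpm`
would return on that fold.

Significance is assessed two ways, following standard practice for
classification pipelines: a label-permutation null (the full pipeline is
re-run on shuffled labels B times, and the add-one estimator
``p = (1 + #{null >= observed}) / (1 + B)`` is reported) and an exact
one-sided sign test that per-subject correctness beats chance 0.5.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning; identical seeds give
bit-identical outcomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import binomtest

from .cpm import (
    DirectionalFeatureSelection,
    Mode,
    _check_mode,
    _check_threshold,
    _fast_selection,
    fit_cpm,
    predict_cpm,
    summarize_features,
)
from .datasets import CohortDataset
from .svm import LinearSVM

__all__ = [
    "CVOutcome",
    "PermutationResult",
    "confusion_and_accuracy",
    "cross_dataset_predict",
    "kfold_cv",
    "loocv",
    "permutation_test",
    "sign_test",
    "threshold_search",
    "DEFAULT_THRESHOLDS",
]

log = logging.getLogger(__name__)

#: The p-threshold grid searched when no single threshold is imposed.
DEFAULT_THRESHOLDS = (0.05, 0.01, 0.005, 0.001)


def confusion_and_accuracy(
    predictions: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, float]:
    """2x2 confusion matrix (rows = true class, cols = predicted) and accuracy."""
    predictions = np.asarray(predictions, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.int64)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    confusion = np.zeros((2, 2), dtype=np.int64)
    np.add.at(confusion, (labels, predictions), 1)
    accuracy = float(np.trace(confusion)) / labels.size
    return confusion, accuracy


@dataclass
class CVOutcome:
    """Out-of-fold predictions and summaries for one evaluation run."""

    predictions: np.ndarray
    labels: np.ndarray
    accuracy: float
    confusion: np.ndarray
    mode: Mode
    threshold: float
    fold_selections: list[DirectionalFeatureSelection] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.predictions.size

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "threshold": self.threshold,
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "n": self.n,
        }


def sign_test(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Exact one-sided binomial test that correctness exceeds chance 0.5.

    p = P(X >= #correct) for X ~ Binomial(n, 1/2).
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape or predictions.size == 0:
        raise ValueError("predictions and labels must be non-empty and equal length")
    k = int((predictions == labels).sum())
    return float(binomtest(k, predictions.size, 0.5, alternative="greater").pvalue)


def _loocv_stats(edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Label-independent sufficient statistics shared across permutations."""
    sx = edges.sum(axis=0)
    sxx = np.einsum("ij,ij->j", edges, edges)
    return sx, sxx


def _loocv_core(
    edges: np.ndarray,
    labels: np.ndarray,
    mode: Mode,
    threshold: float,
    C: float,
    sx: np.ndarray,
    sxx: np.ndarray,
    keep_selections: bool = True,
) -> tuple[np.ndarray, list[DirectionalFeatureSelection]]:
    """One full LOOCV pass; per-fold correlations via downdated sums."""
    n = labels.size
    m = n - 1
    y = labels.astype(float)
    xty = edges.T @ y
    sy = float(y.sum())
    preds = np.empty(n, dtype=np.int64)
    selections: list[DirectionalFeatureSelection] = []
    var_floor = 1e-12
    for s in range(n):
        xs = edges[s]
        ys = y[s]
        sx_f = sx - xs
        sxx_f = sxx - xs * xs
        sxy_f = xty - xs * ys
        sy_f = sy - ys
        # binary labels: syy == sy, so label variance is sy(1 - sy/m)
        vary = sy_f * (1.0 - sy_f / m)
        varx = sxx_f - sx_f * sx_f / m
        cov = sxy_f - sx_f * (sy_f / m)
        cut = var_floor * np.maximum(sxx_f, 1.0)
        ok = varx > cut
        r = np.zeros(edges.shape[1])
        np.divide(cov, np.sqrt(np.maximum(varx, cut) * vary), out=r, where=ok)
        np.clip(r, -1.0, 1.0, out=r)
        sel = _fast_selection(r, m - 2, threshold)
        # summary features for all subjects at once; train rows are then a
        # cheap row subset (identical values to summarizing the fold alone)
        features, empty = summarize_features(edges, sel, mode)
        train = np.arange(n) != s
        if bool(empty.all()):
            counts = np.bincount(labels[train], minlength=2)
            preds[s] = 1 if counts[1] > counts[0] else 0
        else:
            clf = LinearSVM(C=C).fit(features[train], labels[train])
            preds[s] = clf.predict(features[s : s + 1])[0]
        if keep_selections:
            selections.append(sel)
    return preds, selections


def loocv(
    data: CohortDataset,
    mode: Mode,
    threshold: float,
    C: float = 1.0,
) -> CVOutcome:
    """Leave-one-subject-out cross-validation of the full pipeline."""
    _check_mode(mode)
    _check_threshold(threshold)
    if data.n_subjects < 4:
        raise ValueError("LOOCV needs at least 4 subjects")
    nc, np_ = data.class_counts()
    if min(nc, np_) < 2:
        raise ValueError(
            "a class has < 2 members; LOOCV folds would be single-class "
            "(consider stratified k-fold)"
        )
    sx, sxx = _loocv_stats(data.edges)
    preds, sels = _loocv_core(data.edges, data.labels, mode, threshold, C, sx, sxx)
    confusion, accuracy = confusion_and_accuracy(preds, data.labels)
    return CVOutcome(preds, data.labels.copy(), accuracy, confusion, mode,
                     float(threshold), sels)


def _stratified_folds(
    labels: np.ndarray, k: int, seed: int
) -> list[np.ndarray]:
    """Class-stratified fold index sets from a seeded shuffle."""
    rng = np.random.default_rng(seed)
    parts: list[list[np.ndarray]] = []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        parts.append(np.array_split(idx, k))
    folds = [np.sort(np.concatenate([parts[0][f], parts[1][f]])) for f in range(k)]
    return folds


def kfold_cv(
    data: CohortDataset,
    mode: Mode,
    threshold: float,
    k: int = 10,
    C: float = 1.0,
    seed: int = 0,
) -> CVOutcome:
    """Stratified k-fold cross-validation; ``k = n`` degenerates to LOOCV."""
    _check_mode(mode)
    _check_threshold(threshold)
    n = data.n_subjects
    if k < 2:
        raise ValueError("k must be >= 2")
    nc, np_ = data.class_counts()
    if k == n:
        folds = [np.array([s]) for s in range(n)]
    elif min(nc, np_) < k:
        raise ValueError(
            f"smallest class has {min(nc, np_)} members; cannot build {k} "
            "stratified folds"
        )
    else:
        folds = _stratified_folds(data.labels, k, seed)
    preds = np.empty(n, dtype=np.int64)
    selections = []
    all_idx = np.arange(n)
    for fold in folds:
        train_idx = np.setdiff1d(all_idx, fold, assume_unique=True)
        train_labels = data.labels[train_idx]
        if np.unique(train_labels).size < 2:
            raise ValueError("a training fold is single-class; reduce k")
        model = fit_cpm(data.subset(train_idx), mode, threshold, C)
        preds[fold] = predict_cpm(model, data.edges[fold])
        selections.append(model.selection)
    confusion, accuracy = confusion_and_accuracy(preds, data.labels)
    return CVOutcome(preds, data.labels.copy(), accuracy, confusion, mode,
                     float(threshold), selections)


def cross_dataset_predict(
    train: CohortDataset,
    test: CohortDataset,
    mode: Mode,
    threshold: float,
    C: float = 1.0,
) -> CVOutcome:
    """Fit on all of ``train``, predict all of ``test`` (site transfer)."""
    if train.n_edges != test.n_edges:
        raise ValueError(
            f"edge dimension mismatch: train has {train.n_edges}, "
            f"test has {test.n_edges}"
        )
    model = fit_cpm(train, mode, threshold, C)
    preds = predict_cpm(model, test.edges)
    confusion, accuracy = confusion_and_accuracy(preds, test.labels)
    return CVOutcome(preds, test.labels.copy(), accuracy, confusion, mode,
                     float(threshold), [model.selection])


def threshold_search(
    data: CohortDataset,
    mode: Mode,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    C: float = 1.0,
) -> tuple[float, dict[float, CVOutcome]]:
    """LOOCV at each candidate p-threshold; returns the most accurate one.

    Ties are broken toward the smallest threshold (the sparser, more
    conservative selection).  Note the winning accuracy is optimistically
    biased because the search and the evaluation share the dataset; the
    search table is returned so reports can show all candidates.
    """
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    table = {float(t): loocv(data, mode, t, C) for t in thresholds}
    best = min(table, key=lambda t: (-table[t].accuracy, t))
    return best, table


@dataclass
class PermutationResult:
    """Observed accuracy against a label-shuffle null distribution."""

    observed_accuracy: float
    null_accuracies: np.ndarray
    p_value: float
    B: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed_accuracy": self.observed_accuracy,
            "p_value": self.p_value,
            "B": self.B,
            "seed": self.seed,
            "null_mean": float(self.null_accuracies.mean()),
            "null_q95": float(np.quantile(self.null_accuracies, 0.95)),
        }


def permutation_pvalue(observed: float, null_accuracies: np.ndarray) -> float:
    """Add-one permutation p: (1 + #{null >= observed}) / (1 + B)."""
    null_accuracies = np.asarray(null_accuracies, dtype=float)
    B = null_accuracies.size
    return float(1 + int((null_accuracies >= observed).sum())) / (1 + B)


def permutation_test(
    data: CohortDataset,
    mode: Mode,
    threshold: float,
    C: float = 1.0,
    B: int = 1000,
    seed: int = 0,
    evaluator: str = "loocv",
    k: int = 10,
    test: CohortDataset | None = None,
) -> PermutationResult:
    """Label-permutation null for an evaluation procedure.

    ``evaluator`` is one of ``"loocv"``, ``"kfold"`` or
    ``"cross_dataset"`` (the latter shuffles *training* labels and keeps
    the test set fixed).  Each shuffle re-runs the complete pipeline —
    feature selection, summation and classifier fit — under the permuted
    labels.  Shuffles that would create a single-class training set are
    redrawn (a label permutation preserves class counts, so this only
    guards pathological inputs).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    _check_mode(mode)
    _check_threshold(threshold)
    ss = np.random.SeedSequence(seed)
    shuffle_ss, fold_ss = ss.spawn(2)
    rng = np.random.default_rng(shuffle_ss)
    fold_seed = int(fold_ss.generate_state(1)[0] % (2**31))

    if evaluator == "loocv":
        sx, sxx = _loocv_stats(data.edges)

        def run(labels: np.ndarray) -> float:
            preds, _ = _loocv_core(
                data.edges, labels, mode, threshold, C, sx, sxx,
                keep_selections=False,
            )
            return confusion_and_accuracy(preds, labels)[1]

    elif evaluator == "kfold":

        def run(labels: np.ndarray) -> float:
            shuffled = CohortDataset(
                data.subject_ids, data.edges, labels, n_nodes=data.n_nodes
            )
            return kfold_cv(shuffled, mode, threshold, k=k, C=C, seed=fold_seed).accuracy

    elif evaluator == "cross_dataset":
        if test is None:
            raise ValueError("cross_dataset evaluator requires a test cohort")

        def run(labels: np.ndarray) -> float:
            shuffled = CohortDataset(
                data.subject_ids, data.edges, labels, n_nodes=data.n_nodes
            )
            return cross_dataset_predict(shuffled, test, mode, threshold, C).accuracy

    else:
        raise ValueError(f"unknown evaluator {evaluator!r}")

    observed = run(data.labels)
    nulls = np.empty(B)
    for b in range(B):
        for _ in range(1000):
            perm = rng.permutation(data.n_subjects)
            shuffled = data.labels[perm]
            if np.unique(shuffled).size == 2:
                break
            log.info("degenerate shuffle redrawn at b=%d", b)
        nulls[b] = run(shuffled)
    p = permutation_pvalue(observed, nulls)
    return PermutationResult(observed, nulls, p, B, seed)
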