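"""Core of the modified CPM: directional edge selection and the margin classifier.

The protocol, per training set:

1. Point-biserially correlate every edge with the binary group label
   (patient = 1, control = 0).
2. Keep edges whose two-sided p falls below a threshold, split them by
   the sign of r into "increased in patients" and "decreased in
   patients" sets.
3. Sum each subject's selected edge values within each set, collapsing
   tens of thousands of edges to one or two summary features.
4. Fit a soft-margin linear classifier (C = 1 by default, no feature
   standardization) on those features, in one of three modes: only the
   increased sum, only the decreased sum, or both.

Feature selection happens strictly inside the training set; a fitted
model carries its masks and applies them unchanged to test subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.special import stdtr
from scipy.stats import t as _t_dist

from .datasets import CohortDataset
from .svm import LinearSVM

__all__ = [
    "DirectionalFeatureSelection",
    "CpmModel",
    "MODES",
    "edgewise_label_correlation",
    "select_directional_features",
    "summarize_features",
    "fit_cpm",
    "predict_cpm",
]

log = logging.getLogger(__name__)

MODES = ("increased", "decreased", "both")
Mode = Literal["increased", "decreased", "both"]

#: Below this (relative) variance an edge is treated as constant:
#: r = 0, p = 1, never selected.
_VAR_FLOOR = 1e-12

_r_crit_cache: dict[tuple[int, float], float] = {}


def _check_mode(mode: str) -> str:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    return mode


def _check_threshold(threshold: float) -> float:
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"p-threshold must be in (0, 1), got {threshold}")
    return float(threshold)


def _r_critical(df: int, threshold: float) -> float:
    """|r| above which the two-sided p of the point-biserial t is < threshold.

    p < threshold  <=>  |t| > t_crit  <=>  |r| > t_crit / sqrt(t_crit^2 + df),
    an exact monotone reformulation used on hot paths to avoid computing
    full p-vectors that would only be compared against the threshold.
    """
    key = (df, threshold)
    rc = _r_crit_cache.get(key)
    if rc is None:
        tc = float(_t_dist.isf(threshold / 2.0, df))
        rc = tc / np.sqrt(tc * tc + df)
        _r_crit_cache[key] = rc
    return rc


def _corr_only(edges: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Edge-label Pearson r for all edges, constant edges mapped to 0."""
    n = y.size
    yc = y - y.mean()
    syy = float(yc @ yc)
    num = edges.T @ yc
    sx = edges.sum(axis=0)
    sxx = np.einsum("ij,ij->j", edges, edges)
    varx = sxx - sx * sx / n
    cut = _VAR_FLOOR * np.maximum(sxx, 1.0)
    ok = varx > cut
    r = np.zeros(edges.shape[1])
    np.divide(num, np.sqrt(np.maximum(varx, cut) * syy), out=r, where=ok)
    return np.clip(r, -1.0, 1.0)


def p_from_r(r: np.ndarray, df: int) -> np.ndarray:
    """Two-sided p for Pearson r on ``df`` degrees of freedom.

    Uses t = r sqrt(df / (1 - r^2)); |r| = 1 maps to the smallest
    positive float so p stays in (0, 1].
    """
    r = np.asarray(r, dtype=float)
    om = 1.0 - r * r
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(om, 0.0))
    p = np.where(np.isfinite(t), 2.0 * stdtr(df, -np.abs(t)), 0.0)
    return np.maximum(p, np.finfo(float).tiny)


def edgewise_label_correlation(
    edges: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Point-biserial correlation of every edge with the group label.

    Returns ``(r, p)``; p is the two-sided p-value of
    ``t = r sqrt((n-2)/(1-r^2))`` on n-2 degrees of freedom, which is
    identical to the p of an equal-variance two-sample t-test comparing
    the groups on that edge.  Constant edges get r = 0, p = 1.

    Raises
    ------
    ValueError
        If fewer than 4 subjects (df < 2) or the labels are single-class.
    """
    edges = np.asarray(edges, dtype=float)
    labels = np.asarray(labels)
    n = labels.size
    if n < 4:
        raise ValueError(f"need n >= 4 subjects for edgewise correlation, got {n}")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("labels contain a single class; correlation undefined")
    y = labels.astype(float)
    r = _corr_only(edges, y)
    p = np.where(r == 0.0, 1.0, p_from_r(r, n - 2))
    return r, p


@dataclass
class DirectionalFeatureSelection:
    """Per-edge selection result at one p-threshold.

    ``increased_mask`` marks edges with r > 0 (connectivity higher in
    patients) and p < threshold; ``decreased_mask`` the r < 0
    counterpart.  The masks are disjoint by construction.  ``p`` is
    materialized lazily from ``r`` and ``df`` when the selection was
    produced on a hot path that only needed the masks.
    """

    r: np.ndarray
    threshold: float
    increased_mask: np.ndarray
    decreased_mask: np.ndarray
    df: int | None = None
    p_: np.ndarray | None = field(default=None, repr=False)

    @property
    def p(self) -> np.ndarray:
        if self.p_ is None:
            if self.df is None:
                raise ValueError("p-values unavailable: no df recorded")
            self.p_ = np.where(self.r == 0.0, 1.0, p_from_r(self.r, self.df))
        return self.p_

    @property
    def n_edges(self) -> int:
        return self.increased_mask.size

    @property
    def n_increased(self) -> int:
        return int(self.increased_mask.sum())

    @property
    def n_decreased(self) -> int:
        return int(self.decreased_mask.sum())

    def mask(self, direction: str) -> np.ndarray:
        if direction == "increased":
            return self.increased_mask
        if direction == "decreased":
            return self.decreased_mask
        raise ValueError(f"direction must be 'increased' or 'decreased', got {direction!r}")


def select_directional_features(
    r: np.ndarray, p: np.ndarray, threshold: float
) -> DirectionalFeatureSelection:
    """Split significant edges by sign of their label correlation."""
    _check_threshold(threshold)
    r = np.asarray(r, dtype=float)
    p = np.asarray(p, dtype=float)
    if r.shape != p.shape:
        raise ValueError("r and p must have the same shape")
    sig = p < threshold
    return DirectionalFeatureSelection(
        r=r,
        threshold=float(threshold),
        increased_mask=sig & (r > 0),
        decreased_mask=sig & (r < 0),
        p_=p,
    )


def _fast_selection(
    r: np.ndarray, df: int, threshold: float
) -> DirectionalFeatureSelection:
    """Mask construction via the critical-|r| reformulation (no p vector)."""
    rc = _r_critical(df, threshold)
    return DirectionalFeatureSelection(
        r=r,
        threshold=threshold,
        increased_mask=r > rc,
        decreased_mask=r < -rc,
        df=df,
    )


def summarize_features(
    edges: np.ndarray,
    selection: DirectionalFeatureSelection,
    mode: Mode,
) -> tuple[np.ndarray, np.ndarray]:
    """Sum each subject's selected edges into 1 or 2 summary features.

    Returns ``(features, empty)`` where ``features`` is (n_subjects, k)
    with k = 1 for single-direction modes and k = 2 for ``both``
    (columns ordered [increased_sum, decreased_sum]), and ``empty``
    flags columns whose mask selected no edges (those columns are
    identically 0).
    """
    _check_mode(mode)
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 2 or edges.shape[1] != selection.n_edges:
        raise ValueError(
            f"edges have {edges.shape[-1]} columns, selection expects "
            f"{selection.n_edges}"
        )
    directions = ("increased", "decreased") if mode == "both" else (mode,)
    cols = []
    empty = []
    for d in directions:
        idx = np.flatnonzero(selection.mask(d))
        empty.append(idx.size == 0)
        if idx.size:
            cols.append(edges[:, idx].sum(axis=1))
        else:
            cols.append(np.zeros(edges.shape[0]))
    return np.column_stack(cols), np.asarray(empty, dtype=bool)


@dataclass
class CpmModel:
    """A fitted directional CPM: training-derived masks plus the classifier.

    When no edge survived selection for the requested mode, the model
    degenerates to a majority-class predictor (``fallback_label``);
    ties in the training class counts fall back to 0 (control).
    """

    mode: Mode
    threshold: float
    C: float
    selection: DirectionalFeatureSelection
    classifier: LinearSVM | None
    fallback_label: int | None
    feature_empty: np.ndarray
    n_edges: int

    @property
    def is_fallback(self) -> bool:
        return self.fallback_label is not None

    def to_dict(self) -> dict:
        """JSON-serializable form; masks stored as canonical edge indices."""
        d = {
            "mode": self.mode,
            "threshold": self.threshold,
            "C": self.C,
            "n_edges": self.n_edges,
            "increased_edges": np.flatnonzero(self.selection.increased_mask).tolist(),
            "decreased_edges": np.flatnonzero(self.selection.decreased_mask).tolist(),
            "fallback_label": self.fallback_label,
            "feature_empty": self.feature_empty.tolist(),
        }
        if self.classifier is not None:
            d["weights"] = np.asarray(self.classifier.coef_).tolist()
            d["intercept"] = float(self.classifier.intercept_)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CpmModel":
        n_edges = int(d["n_edges"])
        inc = np.zeros(n_edges, dtype=bool)
        dec = np.zeros(n_edges, dtype=bool)
        inc[np.asarray(d["increased_edges"], dtype=int)] = True
        dec[np.asarray(d["decreased_edges"], dtype=int)] = True
        sel = DirectionalFeatureSelection(
            r=np.zeros(n_edges),
            threshold=float(d["threshold"]),
            increased_mask=inc,
            decreased_mask=dec,
        )
        clf = None
        if "weights" in d:
            clf = LinearSVM(C=float(d["C"]))
            clf.coef_ = np.asarray(d["weights"], dtype=float)
            clf.intercept_ = float(d["intercept"])
        fb = d.get("fallback_label")
        return cls(
            mode=d["mode"],
            threshold=float(d["threshold"]),
            C=float(d["C"]),
            selection=sel,
            classifier=clf,
            fallback_label=None if fb is None else int(fb),
            feature_empty=np.asarray(d["feature_empty"], dtype=bool),
            n_edges=n_edges,
        )


def _fit_from_r(
    r: np.ndarray,
    df: int,
    edges: np.ndarray,
    labels: np.ndarray,
    mode: Mode,
    threshold: float,
    C: float,
) -> CpmModel:
    """Shared fitting tail used by :func:`fit_cpm` and the CV fast paths."""
    selection = _fast_selection(r, df, threshold)
    features, empty = summarize_features(edges, selection, mode)
    if bool(empty.all()):
        counts = np.bincount(labels, minlength=2)
        fallback = 1 if counts[1] > counts[0] else 0
        log.warning(
            "no edges survived selection (mode=%s, threshold=%g); "
            "falling back to majority class %d",
            mode,
            threshold,
            fallback,
        )
        return CpmModel(mode, threshold, C, selection, None, fallback, empty, r.size)
    clf = LinearSVM(C=C).fit(features, labels)
    return CpmModel(mode, threshold, C, selection, clf, None, empty, r.size)


def fit_cpm(
    train: CohortDataset,
    mode: Mode,
    threshold: float,
    C: float = 1.0,
) -> CpmModel:
    """Run selection, sign split, summation and classifier fit on a training set."""
    _check_mode(mode)
    _check_threshold(threshold)
    if C <= 0:
        raise ValueError(f"box constraint C must be positive, got {C}")
    if train.n_subjects < 4:
        raise ValueError("need at least 4 training subjects")
    r = _corr_only(train.edges, train.labels.astype(float))
    return _fit_from_r(
        r, train.n_subjects - 2, train.edges, train.labels, mode, threshold, C
    )


def predict_cpm(model: CpmModel, test_edges: np.ndarray) -> np.ndarray:
    """Apply a fitted model's masks and decision rule to test subjects."""
    test_edges = np.asarray(test_edges, dtype=float)
    if test_edges.ndim == 1:
        test_edges = test_edges[None, :]
    if test_edges.shape[1] != model.n_edges:
        raise ValueError(
            f"test edges have {test_edges.shape[1]} columns, model expects "
            f"{model.n_edges}"
        )
    if model.is_fallback:
        return np.full(test_edges.shape[0], model.fallback_label, dtype=np.int64)
    features, _ = summarize_features(test_edges, model.selection, model.mode)
    return model.classifier.predict(features)
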