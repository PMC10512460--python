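"""Soft-margin linear classifier for the 1- and 2-dimensional summary features.

The decision rule the pipeline needs is the classic C-SVM: minimize
``0.5 ||w||^2 + C * sum_i max(0, 1 - y_i (w.x_i + b))`` with an
unpenalized intercept and no feature standardization.  Because the
feature space here is at most two-dimensional and training sets are a
few dozen to a few hundred subjects, the dual problem is tiny; it is
solved by sequential minimal optimization (maximal-violating-pair
working-set selection, the standard pairwise analytic update, and the
usual KKT-interval rule for the intercept).  The solver is jitted with
numba so that resampling procedures that refit the classifier millions
of times (label-permutation nulls over leave-one-out loops) stay cheap.

Determinism: the solver has no random state; identical inputs give
identical (w, b).  Ties on the decision boundary (decision value
exactly 0) are classified as class 1 — an arbitrary but fixed and
documented convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = ["LinearSVM"]

_TAU = 1e-12


@njit(cache=True)
def _smo(K, y, C, tol, max_iter):  # pragma: no cover - exercised via fit()
    n = K.shape[0]
    alpha = np.zeros(n)
    G = -np.ones(n)  # gradient of 0.5 a'Qa - e'a at a, Q_ij = y_i y_j K_ij
    it = 0
    while it < max_iter:
        # maximal violating pair
        Gmax = -1e300
        Gmin = 1e300
        i = -1
        j = -1
        for t in range(n):
            v = -y[t] * G[t]
            if (y[t] > 0 and alpha[t] < C) or (y[t] < 0 and alpha[t] > 0):
                if v >= Gmax:
                    Gmax = v
                    i = t
            if (y[t] > 0 and alpha[t] > 0) or (y[t] < 0 and alpha[t] < C):
                if v <= Gmin:
                    Gmin = v
                    j = t
        if i < 0 or j < 0 or Gmax - Gmin < tol:
            break
        old_i = alpha[i]
        old_j = alpha[j]
        quad = K[i, i] + K[j, j] - 2.0 * K[i, j]
        if quad <= 0.0:
            quad = _TAU
        if y[i] != y[j]:
            delta = (-G[i] - G[j]) / quad
            diff = alpha[i] - alpha[j]
            alpha[i] += delta
            alpha[j] += delta
            if diff > 0.0:
                if alpha[j] < 0.0:
                    alpha[j] = 0.0
                    alpha[i] = diff
                if alpha[i] > C:
                    alpha[i] = C
                    alpha[j] = C - diff
            else:
                if alpha[i] < 0.0:
                    alpha[i] = 0.0
                    alpha[j] = -diff
                if alpha[j] > C:
                    alpha[j] = C
                    alpha[i] = C + diff
        else:
            delta = (G[i] - G[j]) / quad
            s = alpha[i] + alpha[j]
            alpha[i] -= delta
            alpha[j] += delta
            if s > C:
                if alpha[i] > C:
                    alpha[i] = C
                    alpha[j] = s - C
                if alpha[j] > C:
                    alpha[j] = C
                    alpha[i] = s - C
            else:
                if alpha[j] < 0.0:
                    alpha[j] = 0.0
                    alpha[i] = s
                if alpha[i] < 0.0:
                    alpha[i] = 0.0
                    alpha[j] = s
        di = alpha[i] - old_i
        dj = alpha[j] - old_j
        for t in range(n):
            G[t] += y[t] * (y[i] * K[t, i] * di + y[j] * K[t, j] * dj)
        it += 1
    # intercept from the KKT conditions: average of y_t G_t over free
    # support vectors, else the midpoint of the feasible interval
    ub = 1e300
    lb = -1e300
    sum_free = 0.0
    n_free = 0
    for t in range(n):
        yG = y[t] * G[t]
        if alpha[t] >= C:
            if y[t] < 0:
                ub = min(ub, yG)
            else:
                lb = max(lb, yG)
        elif alpha[t] <= 0.0:
            if y[t] > 0:
                ub = min(ub, yG)
            else:
                lb = max(lb, yG)
        else:
            n_free += 1
            sum_free += yG
    rho = sum_free / n_free if n_free > 0 else (ub + lb) / 2.0
    return alpha, rho, it


@dataclass
class LinearSVM:
    """Hinge-loss linear classifier with box constraint ``C``.

    Labels are {0, 1}; internally mapped to {-1, +1}.  ``predict``
    returns 1 where the decision value is >= 0.
    """

    C: float = 1.0
    tol: float = 1e-6
    max_iter: int = 200_000
    coef_: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    intercept_: float = field(default=0.0, repr=False)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearSVM":
        X = np.ascontiguousarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n, d) with one label per row")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"need exactly two classes in y, got {classes.tolist()}")
        if self.C <= 0:
            raise ValueError("C must be positive")
        ys = np.where(y > 0, 1.0, -1.0)
        K = X @ X.T
        alpha, rho, _ = _smo(K, ys, float(self.C), float(self.tol), self.max_iter)
        self.coef_ = X.T @ (alpha * ys)
        self.intercept_ = -float(rho)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) >= 0.0).astype(np.int64)
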