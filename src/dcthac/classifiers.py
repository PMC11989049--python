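"""The three statistical classifiers used on HAC feature vectors.

* :class:`KNNClassifier` — k-nearest neighbors under Euclidean distance,
  k = 1 by default (the conservative choice: only the single closest
  training pattern votes). Ties are broken by the lowest training-row
  index.
* :class:`NaiveBayesClassifier` — naive Bayes with Gaussian per-class,
  per-feature conditional densities (default) or an equal-frequency binned
  multinomial variant; class priors are training frequencies and the
  posterior is maximized in log space.
* :class:`PolynomialSVM` — soft-margin SVM with the degree-2 polynomial
  kernel K(u, v) = (1 + u.v / s)^2, trained by a deterministic sequential
  minimal optimization (SMO) of the dual; prediction is the sign of
  sum_i alpha_i y_i K(x, x_i) + b.

All three are deterministic: identical inputs give identical models and
predictions. ``make_classifier`` builds a fresh instance from a short name,
which is how the evaluation layer and the CLI request them.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .exceptions import ConvergenceError, DataError


def _as_matrix(X, width: int | None = None) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.ndim != 2:
        raise ValueError("features must be 1-D (single query) or 2-D")
    if width is not None and X.shape[1] != width:
        raise ValueError(f"query width {X.shape[1]} != trained width {width}")
    return X if not single else X  # caller uses _single flag separately


def _is_single(X) -> bool:
    return np.asarray(X).ndim == 1


class Standardizer:
    """Per-feature z-scoring fitted on training rows only (anti-leakage)."""

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X) -> "Standardizer":
        X = np.asarray(X, dtype=np.float64)
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0.0] = 1.0  # constant features pass through centered
        self.scale_ = scale
        return self

    def transform(self, X) -> np.ndarray:
        if self.mean_ is None:
            raise DataError("Standardizer used before fit")
        return (np.asarray(X, dtype=np.float64) - self.mean_) / self.scale_


class KNNClassifier:
    """k-nearest-neighbor classifier, Euclidean distance, default k = 1."""

    def __init__(self, k: int = 1) -> None:
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = int(k)
        self.X_: np.ndarray | None = None
        self.y_: np.ndarray | None = None

    def fit(self, X, y: Sequence[str]) -> "KNNClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(list(y), dtype=object)
        if X.ndim != 2 or X.shape[0] == 0:
            raise DataError("training set must contain at least one row")
        if X.shape[0] != y.size:
            raise ValueError("row/label count mismatch")
        if self.k > X.shape[0]:
            raise ValueError("k exceeds the number of training rows")
        self.X_, self.y_ = X, y
        return self

    @property
    def width(self) -> int:
        if self.X_ is None:
            raise DataError("classifier used before fit")
        return self.X_.shape[1]

    def predict(self, X):
        single = _is_single(X)
        Q = _as_matrix(X, self.width)
        # squared Euclidean distances, queries x training rows
        d2 = (
            np.sum(Q**2, axis=1)[:, None]
            - 2.0 * Q @ self.X_.T
            + np.sum(self.X_**2, axis=1)[None, :]
        )
        if self.k == 1:
            # argmin returns the first (lowest-index) minimizer: the tie rule
            idx = np.argmin(d2, axis=1)
            out = self.y_[idx]
        else:
            out = np.empty(Q.shape[0], dtype=object)
            for qi in range(Q.shape[0]):
                order = np.argsort(d2[qi], kind="stable")[: self.k]
                votes: dict[str, int] = {}
                for t in order:
                    votes[self.y_[t]] = votes.get(self.y_[t], 0) + 1
                best = max(votes.values())
                # among tied labels, the one whose closest representative
                # appears first in distance order wins
                for t in order:
                    if votes[self.y_[t]] == best:
                        out[qi] = self.y_[t]
                        break
        return out[0] if single else out


class NaiveBayesClassifier:
    """Naive Bayes with Gaussian (default) or binned-multinomial conditionals.

    The Gaussian variant estimates a per-class, per-feature mean and (MLE)
    variance; variances are floored at ``var_floor_ratio`` times the overall
    feature variance to keep log densities finite. The binned variant
    discretizes each feature into ``n_bins`` equal-frequency bins computed
    on the pooled training rows and uses Laplace-smoothed bin frequencies.
    """

    def __init__(
        self,
        variant: str = "gaussian",
        n_bins: int = 16,
        var_floor_ratio: float = 1e-9,
    ) -> None:
        if variant not in ("gaussian", "multinomial-binned"):
            raise ValueError(f"unknown variant {variant!r}")
        self.variant = variant
        self.n_bins = int(n_bins)
        self.var_floor_ratio = float(var_floor_ratio)
        self.classes_: list[str] | None = None
        self.log_priors_: np.ndarray | None = None
        self.theta_: np.ndarray | None = None
        self.var_: np.ndarray | None = None
        self.bin_edges_: np.ndarray | None = None
        self.log_bin_probs_: np.ndarray | None = None
        self._width: int | None = None

    def fit(self, X, y: Sequence[str]) -> "NaiveBayesClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(list(y), dtype=object)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be 2-D with one label per row")
        classes = sorted(set(y))
        if len(classes) < 2:
            raise ValueError("need at least two classes")
        counts = {c: int(np.sum(y == c)) for c in classes}
        for c, n_c in counts.items():
            if n_c < 2:
                raise DataError(f"class {c!r} has {n_c} training rows; need >= 2")
        self.classes_ = classes
        self._width = X.shape[1]
        self.log_priors_ = np.log(
            np.asarray([counts[c] for c in classes], dtype=np.float64) / y.size
        )
        if self.variant == "gaussian":
            overall_var = np.var(X, axis=0)
            floor = self.var_floor_ratio * overall_var + 1e-300
            theta = np.empty((len(classes), X.shape[1]))
            var = np.empty_like(theta)
            for ci, c in enumerate(classes):
                rows = X[y == c]
                theta[ci] = rows.mean(axis=0)
                var[ci] = np.maximum(np.var(rows, axis=0), floor)
            self.theta_, self.var_ = theta, var
        else:
            qs = np.linspace(0.0, 1.0, self.n_bins + 1)[1:-1]
            self.bin_edges_ = np.quantile(X, qs, axis=0)  # (n_bins-1, D)
            logp = np.empty((len(classes), self.n_bins, X.shape[1]))
            for ci, c in enumerate(classes):
                rows = X[y == c]
                bins = self._digitize(rows)
                for b in range(self.n_bins):
                    logp[ci, b] = np.log(
                        (np.sum(bins == b, axis=0) + 1.0)
                        / (rows.shape[0] + self.n_bins)
                    )
            self.log_bin_probs_ = logp
        return self

    def _digitize(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(X.shape, dtype=np.intp)
        for j in range(X.shape[1]):
            out[:, j] = np.searchsorted(self.bin_edges_[:, j], X[:, j], side="right")
        return out

    def joint_log_likelihood(self, X) -> np.ndarray:
        """log P(class) + sum_i log P(f_i | class), one row per query."""
        if self.classes_ is None:
            raise DataError("classifier used before fit")
        Q = _as_matrix(X, self._width)
        if _is_single(X):
            Q = np.atleast_2d(np.asarray(X, dtype=np.float64))
        n_classes = len(self.classes_)
        jll = np.empty((Q.shape[0], n_classes))
        if self.variant == "gaussian":
            for ci in range(n_classes):
                log_pdf = -0.5 * (
                    np.log(2.0 * np.pi * self.var_[ci])
                    + (Q - self.theta_[ci]) ** 2 / self.var_[ci]
                )
                jll[:, ci] = self.log_priors_[ci] + log_pdf.sum(axis=1)
        else:
            bins = self._digitize(Q)
            cols = np.arange(Q.shape[1])
            for ci in range(n_classes):
                jll[:, ci] = self.log_priors_[ci] + self.log_bin_probs_[
                    ci, bins, cols
                ].sum(axis=1)
        return jll

    def predict(self, X):
        single = _is_single(X)
        jll = self.joint_log_likelihood(X)
        idx = np.argmax(jll, axis=1)  # ties -> first class in sorted order
        out = np.asarray([self.classes_[i] for i in idx], dtype=object)
        return out[0] if single else out


class PolynomialSVM:
    """Binary soft-margin SVM with the degree-2 polynomial kernel.

    Kernel: ``K(u, v) = (1 + u.v / s)**degree`` with scale ``s`` defaulting
    to the feature width. Training runs a deterministic SMO over the dual:
    sweep the training rows in index order, and for each KKT violator pair
    it with the row maximizing ``|E_i - E_j|`` (lowest index on ties); a
    sweep with no update means the KKT conditions hold within ``tol``.
    """

    def __init__(
        self,
        C: float = 1.0,
        degree: int = 2,
        kernel_scale: float | None = None,
        tol: float = 1e-3,
        max_passes: int = 10_000,
    ) -> None:
        if C <= 0:
            raise ValueError("C must be positive")
        self.C = float(C)
        self.degree = int(degree)
        self.kernel_scale = kernel_scale
        self.tol = float(tol)
        self.max_passes = int(max_passes)
        self.classes_: list[str] | None = None
        self.X_: np.ndarray | None = None
        self.y_signed_: np.ndarray | None = None
        self.alpha_: np.ndarray | None = None
        self.b_: float = 0.0
        self._scale: float | None = None

    def _kernel(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        return (1.0 + A @ B.T / self._scale) ** self.degree

    def fit(self, X, y: Sequence[str]) -> "PolynomialSVM":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(list(y), dtype=object)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be 2-D with one label per row")
        classes = sorted(set(y))
        if len(classes) != 2:
            raise ValueError(f"binary SVM needs exactly 2 classes, got {classes}")
        self.classes_ = classes
        self.X_ = X
        self.y_signed_ = np.where(y == classes[1], 1.0, -1.0)
        self._scale = (
            float(self.kernel_scale) if self.kernel_scale else float(X.shape[1])
        )
        self._smo(self._kernel(X, X))
        return self

    def _smo(self, K: np.ndarray) -> None:
        n = K.shape[0]
        y = self.y_signed_
        C, tol = self.C, self.tol
        alpha = np.zeros(n)
        b = 0.0
        def try_pair(i: int, j: int, E: np.ndarray) -> bool:
            """Analytic two-variable update; returns True on progress."""
            nonlocal b
            if y[i] != y[j]:
                lo = max(0.0, alpha[j] - alpha[i])
                hi = min(C, C + alpha[j] - alpha[i])
            else:
                lo = max(0.0, alpha[i] + alpha[j] - C)
                hi = min(C, alpha[i] + alpha[j])
            if lo >= hi:
                return False
            eta = 2.0 * K[i, j] - K[i, i] - K[j, j]
            if eta >= 0.0:  # degenerate direction (identical kernel rows)
                return False
            a_j = float(np.clip(alpha[j] - y[j] * (E[i] - E[j]) / eta, lo, hi))
            if abs(a_j - alpha[j]) < 1e-10:
                return False
            a_i = alpha[i] + y[i] * y[j] * (alpha[j] - a_j)
            # snap round-off crumbs onto the box bounds
            if a_i < 1e-12:
                a_i = 0.0
            elif a_i > C - 1e-12:
                a_i = C
            if a_j < 1e-12:
                a_j = 0.0
            elif a_j > C - 1e-12:
                a_j = C
            b1 = (
                b - E[i]
                - y[i] * (a_i - alpha[i]) * K[i, i]
                - y[j] * (a_j - alpha[j]) * K[i, j]
            )
            b2 = (
                b - E[j]
                - y[i] * (a_i - alpha[i]) * K[i, j]
                - y[j] * (a_j - alpha[j]) * K[j, j]
            )
            alpha[i], alpha[j] = a_i, a_j
            if 0.0 < a_i < C:
                b = b1
            elif 0.0 < a_j < C:
                b = b2
            else:
                b = 0.5 * (b1 + b2)
            return True

        converged = False
        for _ in range(self.max_passes):
            changed = 0
            violators = 0
            for i in range(n):
                E = (alpha * y) @ K + b - y  # refreshed before each step
                r = E[i] * y[i]
                if not ((r < -tol and alpha[i] < C) or (r > tol and alpha[i] > 0)):
                    continue
                violators += 1
                # second index: largest |E_j - E_i| first, then the rest
                order = np.argsort(-np.abs(E - E[i]), kind="stable")
                for j in order:
                    if j != i and try_pair(i, int(j), E):
                        changed += 1
                        break
            if violators == 0:
                converged = True
                break
            if changed == 0:
                break  # violators remain but no pair can move: stuck
        if not converged:
            # final authoritative check before declaring failure
            E = (alpha * y) @ K + b - y
            r = E * y
            stuck = np.any(
                ((r < -tol) & (alpha < C)) | ((r > tol) & (alpha > 0))
            )
            if stuck:
                raise ConvergenceError(
                    f"SMO did not satisfy KKT within tol={tol} "
                    f"after {self.max_passes} passes"
                )
        self.alpha_ = alpha
        self.b_ = float(b)

    def decision_function(self, X) -> np.ndarray:
        if self.alpha_ is None:
            raise DataError("classifier used before fit")
        Q = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if Q.shape[1] != self.X_.shape[1]:
            raise ValueError(
                f"query width {Q.shape[1]} != trained width {self.X_.shape[1]}"
            )
        return self._kernel(Q, self.X_) @ (self.alpha_ * self.y_signed_) + self.b_

    def kkt_violation(self) -> float:
        """Largest KKT violation on the training set (diagnostic)."""
        margins = self.y_signed_ * self.decision_function(self.X_)
        viol = np.zeros_like(margins)
        free = (self.alpha_ > 0) & (self.alpha_ < self.C)
        viol[self.alpha_ == 0] = np.maximum(0.0, 1.0 - margins[self.alpha_ == 0])
        viol[free] = np.abs(1.0 - margins[free])
        at_c = self.alpha_ >= self.C
        viol[at_c] = np.maximum(0.0, margins[at_c] - 1.0)
        return float(viol.max())

    def predict(self, X):
        single = _is_single(X)
        dec = self.decision_function(X)
        out = np.asarray(
            [self.classes_[1] if d > 0 else self.classes_[0] for d in dec],
            dtype=object,
        )
        return out[0] if single else out


def make_classifier(kind: str, **params):
    """Build a fresh classifier from its short name: knn, nb or svm."""
    kind = kind.lower()
    if kind == "knn":
        return KNNClassifier(**params)
    if kind == "nb":
        return NaiveBayesClassifier(**params)
    if kind == "svm":
        return PolynomialSVM(**params)
    raise ValueError(f"unknown classifier {kind!r}; expected knn, nb or svm")
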