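"""Statistical validation of class-averaged HAC features.

The screening experiment averages the HAC feature vectors within each class
(element-wise, giving one mean coefficient vector per class) and asks
whether the pathological and normal mean vectors differ:

* a two-sample F test compares their variances (statistic ``s_a^2 / s_b^2``
  against the F distribution with ``(n_a - 1, n_b - 1)`` degrees of
  freedom, two-tailed);
* a two-sample Kolmogorov-Smirnov test compares their empirical
  distributions (statistic ``D = sup |ECDF_a - ECDF_b|``, asymptotic
  p-value from the Kolmogorov distribution at effective sample size
  ``n_a n_b / (n_a + n_b)``).

Both tests use alpha = 0.05 by default. Note the two "samples" are the two
class-mean vectors themselves (e.g. 500 averaged coefficients each), not
record-level poolings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.special
import scipy.stats

from .dct_features import FeatureMatrix
from .exceptions import DataError
from .signal_io import normalize_label

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class ClassMeanVector:
    """Element-wise mean HAC vector of one class."""

    label: str
    values: np.ndarray


@dataclass(frozen=True)
class TestResult:
    """Outcome of one two-sample test.

    ``df`` is the (numerator, denominator) degrees-of-freedom pair for the
    F test and ``None`` for the KS test.
    """

    test: str
    statistic: float
    p_value: float
    alpha: float = DEFAULT_ALPHA
    df: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def reject(self) -> bool:
        """Reject the null (equal variance / equal distribution) at alpha."""
        return bool(self.p_value < self.alpha)

    def to_dict(self) -> dict:
        out = {
            "test": self.test,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "alpha": float(self.alpha),
            "reject": self.reject,
        }
        if self.df is not None:
            out["df"] = [int(self.df[0]), int(self.df[1])]
        return out


def class_mean_vector(matrix: FeatureMatrix, label: str) -> ClassMeanVector:
    """Element-wise mean of all feature rows carrying `label`."""
    label = normalize_label(label)
    rows = matrix.rows_for_label(label)
    if rows.shape[0] == 0:
        raise ValueError(f"no rows labeled {label!r} in the feature matrix")
    return ClassMeanVector(label=label, values=rows.mean(axis=0))


def two_sample_f_test(
    a: Iterable[float], b: Iterable[float], alpha: float = DEFAULT_ALPHA
) -> TestResult:
    """Two-tailed two-sample F test for equality of variances.

    statistic = var(a) / var(b) with unbiased (n-1) sample variances;
    p = 2 * min(P(F <= f), P(F >= f)) under F(n_a - 1, n_b - 1).
    """
    a = np.asarray(list(a) if not isinstance(a, np.ndarray) else a, dtype=np.float64)
    b = np.asarray(list(b) if not isinstance(b, np.ndarray) else b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise DataError("each sample needs at least 2 observations")
    va = float(np.var(a, ddof=1))
    vb = float(np.var(b, ddof=1))
    if va == 0.0 or vb == 0.0:
        raise DataError("degenerate sample: zero variance")
    f = va / vb
    df = (a.size - 1, b.size - 1)
    cdf = float(scipy.stats.f.cdf(f, *df))
    p = min(1.0, 2.0 * min(cdf, 1.0 - cdf))
    return TestResult(test="F", statistic=f, p_value=p, alpha=alpha, df=df)


def ks_statistic(a: Sequence[float], b: Sequence[float]) -> float:
    """Exact two-sample KS statistic D = sup_x |ECDF_a(x) - ECDF_b(x)|."""
    a = np.sort(np.asarray(a, dtype=np.float64))
    b = np.sort(np.asarray(b, dtype=np.float64))
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    return float(np.max(np.abs(cdf_a - cdf_b)))


def two_sample_ks_test(
    a: Iterable[float],
    b: Iterable[float],
    alpha: float = DEFAULT_ALPHA,
    method: str = "asymp",
) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test.

    ``method="asymp"`` (default) evaluates the asymptotic Kolmogorov
    survival function at ``sqrt(n_eff) * D`` with
    ``n_eff = n_a n_b / (n_a + n_b)``; ``method="exact"`` defers to the
    exact small-sample distribution (useful in tests).
    """
    a = np.asarray(list(a) if not isinstance(a, np.ndarray) else a, dtype=np.float64)
    b = np.asarray(list(b) if not isinstance(b, np.ndarray) else b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise DataError("samples must be non-empty")
    d = ks_statistic(a, b)
    if method == "asymp":
        n_eff = a.size * b.size / (a.size + b.size)
        p = float(scipy.special.kolmogorov(np.sqrt(n_eff) * d))
    elif method == "exact":
        p = float(scipy.stats.ks_2samp(a, b, method="exact").pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    p = min(1.0, max(0.0, p))
    return TestResult(test="KS", statistic=d, p_value=p, alpha=alpha)


def validate_classes(
    matrix: FeatureMatrix,
    pathological_label: str,
    normal_label: str = "NSR",
    alpha: float = DEFAULT_ALPHA,
    ks_method: str = "asymp",
) -> tuple[TestResult, TestResult]:
    """Compare the pathological and normal class-mean HAC vectors.

    Returns ``(f_result, ks_result)`` where the two test samples are the
    element-wise class means (one value per retained coefficient).
    """
    mean_path = class_mean_vector(matrix, pathological_label).values
    mean_norm = class_mean_vector(matrix, normal_label).values
    f_res = two_sample_f_test(mean_path, mean_norm, alpha=alpha)
    ks_res = two_sample_ks_test(mean_path, mean_norm, alpha=alpha, method=ks_method)
    return f_res, ks_res
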