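"""Orthonormal DCT compression and high-amplitude-coefficient features.

The transform is the orthonormal DCT-II of a length-``N`` signal ``x``:

    y(k) = sqrt(2/N) * sum_{n=1..N} x(n) * (1 + delta_{k,1})^{-1/2}
           * cos( pi * (2n - 1) * (k - 1) / (2N) ),   k = 1..M,

i.e. the first coefficient is scaled by an extra 1/sqrt(2) so the basis is
orthonormal (Parseval holds exactly at M = N). Compression keeps only the
first ``M`` coefficients of the *full-length* transform; the feature vector
is then the positional first half of those — the high-amplitude
coefficients (HAC), where the low-frequency energy of the ECG concentrates.
No detrending, windowing or per-record normalization is applied before the
transform.

Coefficient indexing is 1-based (``c1..cD``) in every interface and report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import scipy.fft

from .exceptions import DataError
from .signal_io import LABELS, SignalDataset, normalize_label


@dataclass(frozen=True)
class DCTSpectrum:
    """The first M orthonormal DCT-II coefficients y(1..M) of one record."""

    coefficients: np.ndarray
    source_length: int
    record_id: str | None = None

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.coefficients, dtype=np.float64)
        if coeffs.ndim != 1 or coeffs.size == 0:
            raise ValueError("coefficients must be a non-empty 1-D sequence")
        if coeffs.size > self.source_length:
            raise ValueError("more coefficients than source samples")
        if not np.all(np.isfinite(coeffs)):
            raise DataError("non-finite DCT coefficients")
        object.__setattr__(self, "coefficients", coeffs)

    @property
    def n_coefficients(self) -> int:
        return int(self.coefficients.size)


def dct_orthonormal(
    x: Iterable[float],
    num_coefficients: int | None = None,
    record_id: str | None = None,
) -> DCTSpectrum:
    """Orthonormal DCT-II of `x`, truncated to its first `num_coefficients`.

    ``num_coefficients=None`` keeps the full length-N spectrum. The fast
    FFT-based routine is used; it matches the direct double-sum definition
    to better than 1e-9 relative error.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("x must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(x)):
        raise DataError("input signal contains non-finite values")
    n = x.size
    m = n if num_coefficients is None else int(num_coefficients)
    if not 1 <= m <= n:
        raise ValueError(f"num_coefficients must be in [1, {n}], got {m}")
    y = scipy.fft.dct(x, type=2, norm="ortho")[:m]
    return DCTSpectrum(coefficients=y, source_length=n, record_id=record_id)


def idct_orthonormal(y: Iterable[float]) -> np.ndarray:
    """Inverse of :func:`dct_orthonormal` at full length (M = N)."""
    y = np.asarray(y, dtype=np.float64)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("y must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(y)):
        raise DataError("spectrum contains non-finite values")
    return scipy.fft.idct(y, type=2, norm="ortho")


def extract_hac(
    spectrum: DCTSpectrum | Iterable[float], fraction: float = 0.5
) -> np.ndarray:
    """The high-amplitude coefficients: the positional first
    ``floor(fraction * M)`` entries of the truncated spectrum.

    With the full-scale defaults (M = 1000, fraction 0.5) this is
    coefficients 1..500.
    """
    coeffs = (
        spectrum.coefficients
        if isinstance(spectrum, DCTSpectrum)
        else np.asarray(spectrum, dtype=np.float64)
    )
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    width = int(math.floor(fraction * coeffs.size))
    if width == 0:
        raise ValueError(
            f"fraction {fraction} of {coeffs.size} coefficients keeps none"
        )
    return coeffs[:width].copy()


@dataclass
class FeatureMatrix:
    """HAC feature vectors (rows) aligned with labels and record ids."""

    values: np.ndarray
    labels: list[str]
    record_ids: list[str]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if values.shape[0] != len(self.labels) or values.shape[0] != len(
            self.record_ids
        ):
            raise ValueError("row count must match labels and record_ids")
        if values.size and not np.all(np.isfinite(values)):
            raise DataError("feature matrix contains non-finite values")
        self.values = values
        self.labels = [normalize_label(l) for l in self.labels]

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return int(self.values.shape[1])

    @property
    def present_labels(self) -> list[str]:
        present = set(self.labels)
        return [lab for lab in LABELS if lab in present]

    def rows_for_label(self, label: str) -> np.ndarray:
        label = normalize_label(label)
        mask = np.asarray([l == label for l in self.labels])
        return self.values[mask]

    def subset(self, labels: Iterable[str]) -> "FeatureMatrix":
        keep = {normalize_label(l) for l in labels}
        idx = [i for i, l in enumerate(self.labels) if l in keep]
        return FeatureMatrix(
            values=self.values[idx],
            labels=[self.labels[i] for i in idx],
            record_ids=[self.record_ids[i] for i in idx],
        )


def build_feature_matrix(
    dataset: SignalDataset,
    num_coefficients: int = 1000,
    hac_fraction: float = 0.5,
    transform: str = "full-signal",
) -> FeatureMatrix:
    """Compress every record to its HAC feature vector.

    Parameters
    ----------
    num_coefficients : int, default 1000
        M, the number of DCT coefficients retained per record.
    hac_fraction : float, default 0.5
        Fraction of the retained coefficients kept as features (first half).
    transform : {"full-signal", "truncated-signal"}
        ``full-signal`` (default) computes the length-N transform of the
        whole record and keeps its first M coefficients. The alternative
        reading, ``truncated-signal``, transforms only the first M samples.
    """
    if transform not in ("full-signal", "truncated-signal"):
        raise ValueError(f"unknown transform mode {transform!r}")
    m = int(num_coefficients)
    rows: list[np.ndarray] = []
    for rec in dataset:
        if rec.n_samples < m:
            raise DataError(
                f"record {rec.record_id!r} has {rec.n_samples} samples, "
                f"fewer than num_coefficients={m}"
            )
        if transform == "full-signal":
            spectrum = dct_orthonormal(rec.samples, m, record_id=rec.record_id)
        else:
            spectrum = dct_orthonormal(rec.samples[:m], m, record_id=rec.record_id)
        rows.append(extract_hac(spectrum, hac_fraction))
    width = rows[0].size if rows else 0
    values = np.asarray(rows, dtype=np.float64).reshape(len(rows), width)
    return FeatureMatrix(
        values=values,
        labels=[r.label for r in dataset],
        record_ids=[r.record_id for r in dataset],
    )
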