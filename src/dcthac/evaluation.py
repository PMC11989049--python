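"""Two-class evaluation protocol: stratified 10-fold cross-validation.

Each comparison (ARR vs NSR, CHF vs NSR) is scored by accuracy, sensitivity
(true-positive rate on the pathological class) and specificity
(true-negative rate on the normal class), reported as mean +/- standard
deviation over the folds. Folds are stratified: within each class, records
are shuffled with a seeded generator and dealt round-robin, so per-class
fold sizes differ by at most one and every test fold contains both classes.
Wall-clock time per classifier is measured and reported for information
only; it is hardware-dependent and never asserted.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .classifiers import Standardizer, make_classifier
from .dct_features import FeatureMatrix, build_feature_matrix
from .signal_io import SignalDataset, normalize_label
from .stats_validation import TestResult, validate_classes

SCHEMA_VERSION = 1

#: Canonical two-class comparisons: positive (pathological) vs negative.
COMPARISONS = {
    "ARR-VS-NS": ("ARR", "NSR"),
    "ARR-VS-NSR": ("ARR", "NSR"),
    "CHF-VS-NS": ("CHF", "NSR"),
    "CHF-VS-NSR": ("CHF", "NSR"),
}


def parse_comparison(name: str) -> tuple[str, str]:
    """Resolve a comparison name like ``ARR-vs-NS`` to (positive, negative)."""
    key = name.strip().upper()
    if key not in COMPARISONS:
        raise ValueError(
            f"unknown comparison {name!r}; expected ARR-vs-NS or CHF-vs-NS"
        )
    return COMPARISONS[key]


@dataclass(frozen=True)
class ConfusionCounts:
    """Standard 2x2 confusion counts with positive = pathological class."""

    tp: int
    fp: int
    tn: int
    fn: int
    positive_label: str

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


class Metrics(NamedTuple):
    accuracy: float
    sensitivity: float
    specificity: float


def stratified_folds(
    labels: Sequence[str], n_folds: int = 10, seed: int = 1
) -> np.ndarray:
    """Assign each record to one of `n_folds` test folds, stratified by class.

    Within each class the record indices are shuffled with
    ``numpy.random.default_rng(seed)`` and dealt round-robin, so per-class
    fold sizes differ by at most one. Deterministic given (labels, seed).
    """
    labels = [normalize_label(l) for l in labels]
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(labels), dtype=np.intp)
    for lab in sorted(set(labels)):
        idx = np.asarray([i for i, l in enumerate(labels) if l == lab])
        if idx.size < n_folds:
            raise ValueError(
                f"class {lab!r} has {idx.size} records, fewer than "
                f"n_folds={n_folds}"
            )
        idx = rng.permutation(idx)
        assignment[idx] = np.arange(idx.size) % n_folds
    return assignment


def confusion(
    predicted: Sequence[str], truth: Sequence[str], positive_label: str
) -> ConfusionCounts:
    """Count TP/FP/TN/FN with `positive_label` as the positive class."""
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth must have equal length")
    pos = normalize_label(positive_label)
    tp = fp = tn = fn = 0
    for p, t in zip(predicted, truth):
        p, t = normalize_label(p), normalize_label(t)
        if t == pos:
            tp += p == pos
            fn += p != pos
        else:
            tn += p != pos
            fp += p == pos
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, positive_label=pos)


def metrics(counts: ConfusionCounts) -> Metrics:
    """Accuracy, sensitivity and specificity from confusion counts.

    A ratio with zero denominator is reported as NaN, never silently 0.
    """
    if counts.total == 0:
        raise ValueError("no evaluated records")
    acc = (counts.tp + counts.tn) / counts.total
    sens = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else float("nan")
    spec = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else float("nan")
    return Metrics(acc, sens, spec)


@dataclass
class CVSummary:
    """Per-fold and aggregate metrics for one classifier on one comparison."""

    classifier: str
    positive_label: str
    n_folds: int
    seed: int
    fold_metrics: list[Metrics]
    wall_time_s: float
    std_ddof: int = 0
    standardized: bool = False

    def _agg(self, attr: str) -> tuple[float, float]:
        vals = np.asarray([getattr(m, attr) for m in self.fold_metrics])
        return float(np.mean(vals)), float(np.std(vals, ddof=self.std_ddof))

    @property
    def accuracy(self) -> tuple[float, float]:
        return self._agg("accuracy")

    @property
    def sensitivity(self) -> tuple[float, float]:
        return self._agg("sensitivity")

    @property
    def specificity(self) -> tuple[float, float]:
        return self._agg("specificity")

    def to_dict(self) -> dict:
        """Deterministic summary; wall time is reported separately because
        it varies run to run."""
        out: dict = {
            "classifier": self.classifier,
            "positive_label": self.positive_label,
            "n_folds": self.n_folds,
            "fold_seed": self.seed,
            "std_ddof": self.std_ddof,
            "standardized": self.standardized,
            "folds": [
                {
                    "accuracy": m.accuracy,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                }
                for m in self.fold_metrics
            ],
        }
        for name in ("accuracy", "sensitivity", "specificity"):
            mean, std = self._agg(name)
            out[name] = {"mean": mean, "std": std}
        return out


def cross_validate(
    matrix: FeatureMatrix,
    positive_label: str,
    classifier: str = "knn",
    classifier_params: Mapping | None = None,
    n_folds: int = 10,
    seed: int = 1,
    standardize: bool = False,
    std_ddof: int = 0,
) -> CVSummary:
    """Stratified k-fold cross-validation of one classifier.

    Every record is tested exactly once. When ``standardize`` is set, the
    z-scoring statistics are fitted on the training folds only and applied
    to the held-out fold (no leakage).
    """
    labels = matrix.labels
    present = sorted(set(labels))
    if len(present) != 2:
        raise ValueError(f"cross_validate needs exactly two classes, got {present}")
    pos = normalize_label(positive_label)
    if pos not in present:
        raise ValueError(f"positive label {pos!r} absent from the matrix")

    params = dict(classifier_params or {})
    assignment = stratified_folds(labels, n_folds=n_folds, seed=seed)
    y = np.asarray(labels, dtype=object)

    fold_metrics: list[Metrics] = []
    t0 = time.perf_counter()
    for f in range(n_folds):
        test_mask = assignment == f
        X_train, X_test = matrix.values[~test_mask], matrix.values[test_mask]
        y_train, y_test = y[~test_mask], y[test_mask]
        if standardize:
            scaler = Standardizer().fit(X_train)
            X_train = scaler.transform(X_train)
            X_test = scaler.transform(X_test)
        model = make_classifier(classifier, **params)
        model.fit(X_train, y_train)
        pred = model.predict(X_test)
        fold_metrics.append(metrics(confusion(pred, y_test, pos)))
    wall = time.perf_counter() - t0

    return CVSummary(
        classifier=classifier,
        positive_label=pos,
        n_folds=n_folds,
        seed=seed,
        fold_metrics=fold_metrics,
        wall_time_s=wall,
        std_ddof=std_ddof,
        standardized=standardize,
    )


def run_pipeline(
    dataset: SignalDataset,
    comparison: str,
    num_coefficients: int = 1000,
    hac_fraction: float = 0.5,
    classifiers: Sequence[str] = ("knn", "nb", "svm"),
    classifier_params: Mapping[str, Mapping] | None = None,
    n_folds: int = 10,
    seed: int = 1,
    alpha: float = 0.05,
    standardize: bool = False,
) -> dict:
    """End-to-end screen: subset to the two classes, extract HAC features,
    run the F/KS validation, then cross-validate each requested classifier.

    Returns ``{"report": <deterministic>, "timing": <wall times>}``; the
    ``report`` half is byte-stable for identical inputs and seeds.
    """
    pos, neg = parse_comparison(comparison)
    counts = dataset.class_counts
    for lab in (pos, neg):
        if counts.get(lab, 0) == 0:
            raise ValueError(f"comparison {comparison!r}: no {lab} records in dataset")

    subset = dataset.subset([pos, neg])
    matrix = build_feature_matrix(
        subset, num_coefficients=num_coefficients, hac_fraction=hac_fraction
    )
    f_res, ks_res = validate_classes(matrix, pos, neg, alpha=alpha)

    params = dict(classifier_params or {})
    summaries: dict[str, CVSummary] = {}
    for name in classifiers:
        summaries[name] = cross_validate(
            matrix,
            pos,
            classifier=name,
            classifier_params=params.get(name),
            n_folds=n_folds,
            seed=seed,
            standardize=standardize,
        )

    report = {
        "schema_version": SCHEMA_VERSION,
        "config": {
            "comparison": f"{pos}-vs-{neg}",
            "num_coefficients": int(num_coefficients),
            "hac_fraction": float(hac_fraction),
            "n_folds": int(n_folds),
            "fold_seed": int(seed),
            "alpha": float(alpha),
            "standardize": bool(standardize),
            "classifiers": list(classifiers),
            "n_records": len(subset),
            "class_counts": {pos: counts[pos], neg: counts[neg]},
            "stratified": True,
        },
        "statistical_tests": {
            "f_test": f_res.to_dict(),
            "ks_test": ks_res.to_dict(),
        },
        "cross_validation": {name: s.to_dict() for name, s in summaries.items()},
    }
    timing = {name: s.wall_time_s for name, s in summaries.items()}
    return {"report": report, "timing": timing}
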