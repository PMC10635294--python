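"""Gradient-boosted-tree classification of solubility change and normalized
multiclass performance metrics (CPR and generalized squared correlation)."""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "CLASSES",
    "DEFAULT_GBT_PARAMS",
    "LabeledDataset",
    "MetricsReport",
    "train_classifier",
    "confusion_matrix",
    "per_class_counts",
    "normalize_confusion",
    "metrics",
    "cross_validate",
    "save_model",
    "load_model",
    "format_report",
]

#: solubility-change classes: decrease, no change, increase
CLASSES = ("-", "N", "+")

DEFAULT_GBT_PARAMS = dict(
    n_estimators=20000,
    learning_rate=0.05,
    max_depth=7,
    subsample=0.4,
    min_samples_split=3,
    max_features="sqrt",
)

MODEL_FORMAT_VERSION = 1


@dataclass
class LabeledDataset:
    """Feature matrix with class labels in {-, N, +} and sample ids."""

    X: np.ndarray
    y: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=object)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be 2-D with one label per row")
        unknown = set(self.y) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains NaNs")
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(len(self.y))]

    def __len__(self) -> int:
        return len(self.y)


def train_classifier(
    train: LabeledDataset,
    hyperparameters: dict | None = None,
    seed: int = 0,
) -> GradientBoostingClassifier:
    """Fit a gradient-boosted tree ensemble with the stated defaults
    (n_estimators=20000, learning_rate=0.05, max_depth=7, subsample=0.4,
    min_samples_split=3, max_features=sqrt), overridable per key."""
    if len(set(train.y)) < 2:
        raise ValueError("training set must contain at least two classes")
    params = dict(DEFAULT_GBT_PARAMS)
    params.update(hyperparameters or {})
    model = GradientBoostingClassifier(random_state=seed, **params)
    model.fit(train.X, train.y)
    return model


def confusion_matrix(
    truth: Sequence[str], predicted: Sequence[str], classes: Sequence[str] = CLASSES
) -> np.ndarray:
    """K x K counts, entry (i, j) = samples of true class i predicted as j."""
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=float)
    for t, p in zip(truth, predicted, strict=True):
        cm[idx[t], idx[p]] += 1
    return cm


def per_class_counts(cm: np.ndarray, class_index: int) -> tuple[float, float, float, float]:
    """One-vs-rest (TP, TN, FP, FN) for a class of a confusion matrix."""
    cm = np.asarray(cm, dtype=float)
    i = class_index
    tp = cm[i, i]
    fn = cm[i, :].sum() - tp
    fp = cm[:, i].sum() - tp
    tn = cm.sum() - tp - fn - fp
    return tp, tn, fp, fn


def normalize_confusion(cm: np.ndarray) -> np.ndarray:
    """Rescale each row to equal class mass (N/K per true class), countering
    class imbalance while leaving row-internal ratios — and therefore
    sensitivity and specificity — unchanged."""
    cm = np.asarray(cm, dtype=float)
    n = cm.sum()
    k = cm.shape[0]
    row_sums = cm.sum(axis=1)
    if np.any(row_sums <= 0):
        raise ValueError("every true class must have at least one sample")
    return cm * ((n / k) / row_sums)[:, None]


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    """0/0 reported as 0 with a NaN-provenance flag."""
    if den == 0:
        return 0.0, True
    return num / den, False


@dataclass
class MetricsReport:
    """Per-class PPV/NPV/sensitivity/specificity and overall CPR/GC2, each as
    a (raw, normalized) pair; ``nan_flags`` lists metrics whose raw form was
    an undefined 0/0 ratio."""

    ppv: dict[str, tuple[float, float]]
    npv: dict[str, tuple[float, float]]
    sensitivity: dict[str, tuple[float, float]]
    specificity: dict[str, tuple[float, float]]
    cpr: tuple[float, float]
    gc2: tuple[float, float]
    nan_flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "ppv": self.ppv,
            "npv": self.npv,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "cpr": self.cpr,
            "gc2": self.gc2,
            "nan_flags": self.nan_flags,
        }


def _cpr(cm: np.ndarray) -> tuple[float, bool]:
    return _safe_div(np.trace(cm), cm.sum())


def _gc2(cm: np.ndarray) -> tuple[float, bool]:
    n = cm.sum()
    if n == 0:
        return 0.0, True
    k = cm.shape[0]
    x = cm.sum(axis=1)
    y = cm.sum(axis=0)
    e = np.outer(x, y) / n
    mask = e > 0
    chi2 = np.sum((cm[mask] - e[mask]) ** 2 / e[mask])
    return chi2 / (n * (k - 1)), False


def metrics(cm: np.ndarray, classes: Sequence[str] = CLASSES) -> MetricsReport:
    """All metrics on the raw and the row-normalized confusion matrix."""
    cm = np.asarray(cm, dtype=float)
    if cm.size == 0 or cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    ncm = normalize_confusion(cm)
    flags: list[str] = []

    def per_class(fn, name):
        out = {}
        for i, c in enumerate(classes):
            raw, f1 = fn(cm, i)
            norm, _ = fn(ncm, i)
            if f1:
                flags.append(f"{name}[{c}]")
            out[c] = (raw, norm)
        return out

    def ppv(m, i):
        tp, _, fp, _ = per_class_counts(m, i)
        return _safe_div(tp, tp + fp)

    def npv(m, i):
        _, tn, _, fn_ = per_class_counts(m, i)
        return _safe_div(tn, tn + fn_)

    def sens(m, i):
        tp, _, _, fn_ = per_class_counts(m, i)
        return _safe_div(tp, tp + fn_)

    def spec(m, i):
        _, tn, fp, _ = per_class_counts(m, i)
        return _safe_div(tn, tn + fp)

    cpr_raw, _ = _cpr(cm)
    cpr_norm, _ = _cpr(ncm)
    gc2_raw, f = _gc2(cm)
    if f:
        flags.append("gc2")
    gc2_norm, _ = _gc2(ncm)

    return MetricsReport(
        ppv=per_class(ppv, "ppv"),
        npv=per_class(npv, "npv"),
        sensitivity=per_class(sens, "sensitivity"),
        specificity=per_class(spec, "specificity"),
        cpr=(cpr_raw, cpr_norm),
        gc2=(gc2_raw, gc2_norm),
        nan_flags=flags,
    )


@dataclass
class CrossValidationResult:
    """Per-repeat pooled confusion matrices and metric reports, plus the
    mean report over repeats."""

    per_repeat: list[MetricsReport]
    confusions: list[np.ndarray]
    mean: MetricsReport


def _mean_reports(reports: list[MetricsReport]) -> MetricsReport:
    def mean_pair(pairs):
        arr = np.array(pairs)
        return (float(arr[:, 0].mean()), float(arr[:, 1].mean()))

    def mean_dict(key):
        return {
            c: mean_pair([getattr(r, key)[c] for r in reports]) for c in CLASSES
        }

    flags = sorted({f for r in reports for f in r.nan_flags})
    return MetricsReport(
        ppv=mean_dict("ppv"),
        npv=mean_dict("npv"),
        sensitivity=mean_dict("sensitivity"),
        specificity=mean_dict("specificity"),
        cpr=mean_pair([r.cpr for r in reports]),
        gc2=mean_pair([r.gc2 for r in reports]),
        nan_flags=flags,
    )


def cross_validate(
    data: LabeledDataset,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    hyperparameters: dict | None = None,
) -> CrossValidationResult:
    """Stratified k-fold cross-validation with repeated runs.

    Within each repeat the out-of-fold predictions are pooled into one
    confusion matrix before computing metrics (per-fold averaging would bias
    GC2 at small fold sizes); the mean over repeats is reported alongside the
    per-repeat values.
    """
    counts = {c: int(np.sum(data.y == c)) for c in set(data.y)}
    if min(counts.values()) < folds:
        raise ValueError(f"every class needs >= {folds} members, got {counts}")
    reports, confusions = [], []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        cm = np.zeros((len(CLASSES), len(CLASSES)))
        for train_idx, test_idx in skf.split(data.X, data.y.astype(str)):
            model = train_classifier(
                LabeledDataset(data.X[train_idx], data.y[train_idx]),
                hyperparameters,
                seed=seed + r,
            )
            pred = model.predict(data.X[test_idx])
            cm += confusion_matrix(data.y[test_idx], pred)
        confusions.append(cm)
        reports.append(metrics(cm))
    return CrossValidationResult(reports, confusions, _mean_reports(reports))


def save_model(model, path) -> None:
    """Serialize a trained model to a single artifact with a version stamp."""
    with open(path, "wb") as fh:
        pickle.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, fh)


def load_model(path):
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError("unsupported model format version")
    return payload["model"]


def format_report(report: MetricsReport) -> str:
    """Text table of raw/normalized metric pairs."""
    lines = []
    for name in ("ppv", "npv", "sensitivity", "specificity"):
        d = getattr(report, name)
        for c in CLASSES:
            raw, norm = d[c]
            lines.append(f"{name:<12} {c:>2}  {raw:.3f}/{norm:.3f}")
    lines.append(f"{'CPR':<15}  {report.cpr[0]:.3f}/{report.cpr[1]:.3f}")
    lines.append(f"{'GC2':<15}  {report.gc2[0]:.3f}/{report.gc2[1]:.3f}")
    if report.nan_flags:
        lines.append("undefined (0/0, reported as 0): " + ", ".join(report.nan_flags))
    return "\n".join(lines)
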