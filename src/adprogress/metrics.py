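"""Evaluation metrics for marker forecasts and diagnostic classification.

Continuous forecasts are scored by mean absolute error (MAE) and the
weighted error score (WES), where each absolute residual is weighted by
the inverse width of its credible interval — precise predictions are held
to a higher standard.  Categorical predictions are scored from an L x L
confusion matrix (rows = actual, columns = predicted): overall accuracy,
per-class and overall error rates, and balanced classification accuracy

    BCA_l = (sensitivity_l + specificity_l) / 2

computed one-vs-rest per class and averaged over classes; time-resolved
BCAs are aggregated weighted by the number of observations per time point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DX_LABELS
from .errors import ValidationError


@dataclass(frozen=True)
class ErrorScore:
    value: float
    n: int
    metric: str

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValidationError("error scores are non-negative")


def _paired(predicted, observed) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1:
        raise ValidationError("predicted and observed must be equal-length 1-D arrays")
    if len(p) == 0:
        raise ValidationError("empty inputs")
    if not (np.isfinite(p).all() and np.isfinite(o).all()):
        raise ValidationError("non-finite values in inputs")
    return p, o


def mean_absolute_error(predicted, observed) -> ErrorScore:
    """MAE = (1/N) sum |predicted - observed|."""
    p, o = _paired(predicted, observed)
    return ErrorScore(float(np.mean(np.abs(p - o))), len(p), "MAE")


def weighted_error_score(predicted, observed, interval_widths) -> ErrorScore:
    """WES = sum C_i |predicted - observed| / sum C_i with C_i = 1/width_i."""
    p, o = _paired(predicted, observed)
    w = np.asarray(interval_widths, dtype=float)
    if w.shape != p.shape:
        raise ValidationError("interval_widths must match predictions in length")
    if not np.isfinite(w).all() or (w <= 0).any():
        raise ValidationError("interval widths must be strictly positive and finite")
    c = 1.0 / w
    return ErrorScore(float(np.sum(c * np.abs(p - o)) / np.sum(c)), len(p), "WES")


@dataclass
class ConfusionMatrix:
    """L x L diagnosis count table; rows = actual, columns = predicted."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        L = len(self.labels)
        if self.counts.shape != (L, L):
            raise ValidationError("counts must be square with one row per label")
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, label: str) -> tuple[int, int, int, int]:
        """(TP, FN, FP, TN) for the one-vs-rest reduction of class `label`."""
        l = self.labels.index(label)
        tp = int(self.counts[l, l])
        fn = int(self.row_totals[l] - tp)
        fp = int(self.column_totals[l] - tp)
        tn = int(self.total - tp - fn - fp)
        return tp, fn, fp, tn

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


def confusion_matrix(actual, predicted, labels: tuple[str, ...] = DX_LABELS) -> ConfusionMatrix:
    a = np.asarray(actual)
    p = np.asarray(predicted)
    if a.shape != p.shape:
        raise ValidationError("actual and predicted must have equal length")
    pos = {lab: i for i, lab in enumerate(labels)}
    try:
        ai = np.array([pos[x] for x in a])
        pi = np.array([pos[x] for x in p])
    except KeyError as exc:
        raise ValidationError(f"label {exc.args[0]!r} not in {labels}") from None
    L = len(labels)
    counts = np.bincount(ai * L + pi, minlength=L * L).reshape(L, L)
    return ConfusionMatrix(tuple(labels), counts)


def class_error_rates(cm: ConfusionMatrix) -> dict:
    """Per-class error, overall error, and per-cell row percentages."""
    rows = cm.row_totals
    if (rows == 0).any():
        empty = cm.labels[int(np.argmax(rows == 0))]
        raise ValidationError(f"class {empty!r} has no actual observations")
    diag = np.diag(cm.counts)
    per_class = {lab: float((rows[i] - diag[i]) / rows[i]) for i, lab in enumerate(cm.labels)}
    overall = float((cm.total - diag.sum()) / cm.total)
    row_pct = cm.counts / rows[:, None]
    return {"per_class": per_class, "overall": overall, "row_percent": row_pct}


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correct predictions; equals 1 - overall error."""
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def balanced_class_accuracy(cm: ConfusionMatrix, label: str) -> float:
    """Mean of one-vs-rest sensitivity and specificity for one class."""
    tp, fn, fp, tn = cm.one_vs_rest(label)
    if tp + fn == 0 or tn + fp == 0:
        raise ValidationError(f"degenerate one-vs-rest denominators for class {label!r}")
    return 0.5 * (tp / (tp + fn) + tn / (tn + fp))


def overall_bca(cm: ConfusionMatrix) -> float:
    """Unweighted mean of the per-class balanced accuracies."""
    if len(cm.labels) < 2:
        raise ValidationError("overall BCA needs at least two classes")
    return float(np.mean([balanced_class_accuracy(cm, lab) for lab in cm.labels]))


def weighted_aggregate_bca(bca_per_timepoint, n_per_timepoint) -> float:
    """BCA aggregated over time points, weighted by available data."""
    b = np.asarray(bca_per_timepoint, dtype=float)
    n = np.asarray(n_per_timepoint, dtype=float)
    if b.shape != n.shape or b.ndim != 1:
        raise ValidationError("per-timepoint inputs must be equal-length 1-D arrays")
    if (n < 0).any() or n.sum() <= 0:
        raise ValidationError("time-point weights must be non-negative with positive sum")
    return float(np.sum(n * b) / np.sum(n))
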