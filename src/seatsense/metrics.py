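"""Confusion matrices, precision/recall/F1 and the statistical comparisons.

Class averages are macro (unweighted means over classes). Undefined metric
cells (0/0, e.g. a class never predicted) are reported as 0 with a warning
so that reports stay total. Report rounding is 3 decimals, half-up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "EvaluationReport",
    "confusion",
    "precision_recall_f1",
    "f1_score",
    "macro_average",
    "round_half_up",
    "paired_ttest",
    "TTestResult",
    "friedman_test",
    "FriedmanResult",
]


def round_half_up(x: float, decimals: int = 3) -> float:
    """Round with ties away from zero (the convention of printed reports),
    unlike numpy's banker's rounding."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """Square count matrix indexed by (true class, predicted class)."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("confusion matrix must be square over the class order")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise ValueError("class orders differ")
        return ConfusionMatrix(self.counts + other.counts, self.classes)


def confusion(
    y_true: Sequence[str], y_pred: Sequence[str], class_order: Sequence[str]
) -> ConfusionMatrix:
    """Tally (true, predicted) label pairs in a fixed class order."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label sequences differ in length")
    known = set(class_order)
    unknown = {v for v in (*y_true, *y_pred) if v not in known}
    if unknown:
        raise ValueError(f"unknown label(s): {sorted(unknown)}")
    counts = _sk_confusion(y_true, y_pred, labels=list(class_order))
    return ConfusionMatrix(counts, tuple(class_order))


@dataclass
class MetricsReport:
    """Per-class and macro-averaged precision/recall/F1 plus accuracy."""

    classes: tuple[str, ...]
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    accuracy: float
    macro_precision: float = field(init=False)
    macro_recall: float = field(init=False)
    macro_f1: float = field(init=False)

    def __post_init__(self) -> None:
        self.macro_precision = float(np.mean([self.precision[c] for c in self.classes]))
        self.macro_recall = float(np.mean([self.recall[c] for c in self.classes]))
        self.macro_f1 = float(np.mean([self.f1[c] for c in self.classes]))

    def to_frame(self, decimals: int | None = None) -> pd.DataFrame:
        rows = {
            "precision": [self.precision[c] for c in self.classes] + [self.macro_precision],
            "recall": [self.recall[c] for c in self.classes] + [self.macro_recall],
            "f1": [self.f1[c] for c in self.classes] + [self.macro_f1],
        }
        df = pd.DataFrame(rows, index=list(self.classes) + ["average"]).T
        if decimals is not None:
            df = df.map(lambda v: round_half_up(v, decimals))
        return df


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"undefined {what} (0/0) reported as 0", RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def macro_average(values: Sequence[float]) -> float:
    """Unweighted mean over classes or tasks."""
    return float(np.mean(list(values)))


def precision_recall_f1(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts
    precision, recall, f1 = {}, {}, {}
    for j, c in enumerate(cm.classes):
        tp = counts[j, j]
        p = _safe_div(tp, counts[:, j].sum(), f"precision[{c}]")
        r = _safe_div(tp, counts[j, :].sum(), f"recall[{c}]")
        precision[c], recall[c] = float(p), float(r)
        f1[c] = f1_score(p, r)
    accuracy = float(np.trace(counts) / cm.total)
    return MetricsReport(cm.classes, precision, recall, f1, accuracy)


@dataclass
class EvaluationReport:
    """Cross-validation outcome: per-fold and pooled confusions/metrics.

    ``pooled`` computes metrics from the summed confusion matrix (every
    test trial counted once); ``mean_over_folds`` averages the per-fold
    macro metrics instead. ``params`` records per-fold hyperparameters
    (e.g. the selected k).
    """

    classes: tuple[str, ...]
    fold_confusions: list[ConfusionMatrix]
    fold_metrics: list[MetricsReport]
    params: list[dict]
    #: one row per test trial: subject, fold, true label, predicted label
    predictions: pd.DataFrame | None = None

    @property
    def pooled_confusion(self) -> ConfusionMatrix:
        cm = self.fold_confusions[0]
        for other in self.fold_confusions[1:]:
            cm = cm + other
        return cm

    @property
    def pooled(self) -> MetricsReport:
        return precision_recall_f1(self.pooled_confusion)

    @property
    def mean_over_folds(self) -> dict[str, float]:
        return {
            "macro_precision": macro_average([m.macro_precision for m in self.fold_metrics]),
            "macro_recall": macro_average([m.macro_recall for m in self.fold_metrics]),
            "macro_f1": macro_average([m.macro_f1 for m in self.fold_metrics]),
            "accuracy": macro_average([m.accuracy for m in self.fold_metrics]),
        }


@dataclass
class TTestResult:
    statistic: float
    pvalue: float
    degenerate: bool = False


def paired_ttest(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Two-sided paired t-test on per-unit differences.

    Degenerate inputs are handled explicitly: identical pairs give
    ``t = 0, p = 1``; a constant nonzero difference (zero variance) is
    flagged ``degenerate`` with an infinite statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples differ in length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if np.all(d == 0):
            return TTestResult(0.0, 1.0, degenerate=False)
        return TTestResult(float(np.inf) * np.sign(d.mean()), 0.0, degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return TTestResult(float(t), float(p))


@dataclass
class FriedmanResult:
    statistic: float
    pvalue: float


def friedman_test(values: np.ndarray | pd.DataFrame) -> FriedmanResult:
    """Friedman rank test over a complete subjects x conditions table.

    Uses the tie-corrected chi-square form: with within-subject ranks
    ``r_ij`` and rank sums ``R_j``,

        chi2 = (k-1) * sum_j (R_j - n(k+1)/2)^2 / (sum_ij r_ij^2 - n k (k+1)^2 / 4)

    on ``k - 1`` degrees of freedom. Works for k >= 2 conditions. A table
    whose rows are all fully tied has statistic 0 and p = 1.
    """
    table = np.asarray(values, dtype=float)
    if table.ndim != 2:
        raise ValueError("need a 2-D subjects x conditions table")
    n, k = table.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    if np.any(np.isnan(table)):
        raise ValueError("missing cells in the Friedman table")
    ranks = np.apply_along_axis(stats.rankdata, 1, table)
    rank_sums = ranks.sum(axis=0)
    num = (k - 1) * np.sum((rank_sums - n * (k + 1) / 2) ** 2)
    den = np.sum(ranks**2) - n * k * (k + 1) ** 2 / 4
    if den == 0:
        return FriedmanResult(0.0, 1.0)
    chi2 = num / den
    return FriedmanResult(float(chi2), float(stats.chi2.sf(chi2, k - 1)))
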