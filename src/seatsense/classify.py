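"""Classifiers and subject-grouped cross-validation.

Trials from the same person share idiosyncrasies (body mass, sitting
habits), so an honest generalisation estimate must keep every subject's
trials entirely inside either the training or the test split. Folds
therefore partition *subjects* (8 subjects into 4 folds of 2 test
subjects), and feature standardisation is fitted on the training subjects
of each fold only.

Two classifiers operate on the standardised five-feature vectors:

* k-nearest neighbours with Euclidean distance
  ``dist(X, Y) = sqrt(sum_i (x_i - y_i)^2)`` and majority vote; ``k`` is
  chosen by an inner subject-grouped validation sweep.
* a linear soft-margin SVM, ``min 1/2 ||w||^2 (+ C * slack)`` subject to
  ``y_i (w.x_i + b) >= 1 - slack_i``, one-vs-one pairwise machines for
  multiclass (one-vs-rest available).

k-NN tie-breaking is deterministic: among equal distances the lower
training-row index ranks first, and among classes with equal votes the
class of the nearest neighbour wins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from .features import FEATURE_NAMES
from .metrics import ConfusionMatrix, EvaluationReport, confusion, precision_recall_f1

__all__ = [
    "DEFAULT_K_GRID",
    "Standardizer",
    "KNNModel",
    "SVMModel",
    "FoldAssignment",
    "euclidean_distances",
    "select_k",
    "svm_train",
    "make_subject_folds",
    "cross_validate",
    "to_binary_labels",
]

DEFAULT_K_GRID = (1, 3, 5, 7, 9, 11, 13, 15)


@dataclass
class Standardizer:
    """Per-feature zero-mean / unit-variance transform learned on training
    rows (population SD, matching the usual z-score convention)."""

    mean_: np.ndarray
    scale_: np.ndarray
    feature_names: tuple[str, ...] = ()

    @classmethod
    def fit(cls, X: np.ndarray, feature_names: Sequence[str] = ()) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D array with at least 2 rows")
        mean = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        zero = np.flatnonzero(scale == 0)
        if zero.size:
            names = (
                [feature_names[j] for j in zero]
                if feature_names
                else [f"column {j}" for j in zero]
            )
            raise ValueError(f"zero-variance feature(s): {', '.join(map(str, names))}")
        return cls(mean, scale, tuple(feature_names))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_


def euclidean_distances(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distance matrix between row vectors."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    diff = A[:, None, :] - B[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


@dataclass
class KNNModel:
    """k-nearest-neighbour classifier over stored training vectors."""

    k: int
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.k < 1 or self.k > len(self.X):
            raise ValueError(f"k={self.k} outside 1..{len(self.X)} training rows")

    def predict(self, Xq: np.ndarray) -> np.ndarray:
        Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
        dists = euclidean_distances(Xq, self.X)
        out = []
        for row in dists:
            # stable argsort: equal distances rank by training-row index
            order = np.argsort(row, kind="stable")[: self.k]
            votes: dict = {}
            for idx in order:
                votes[self.y[idx]] = votes.get(self.y[idx], 0) + 1
            best = max(votes.values())
            tied = {c for c, v in votes.items() if v == best}
            # among tied classes, the nearest neighbour's class wins
            winner = next(self.y[idx] for idx in order if self.y[idx] in tied)
            out.append(winner)
        return np.array(out)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "seatsense-knn/1",
            "k": int(self.k),
            "X": self.X.tolist(),
            "y": [str(v) for v in self.y],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "KNNModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "seatsense-knn/1":
            raise ValueError("not a seatsense k-NN model file")
        return cls(payload["k"], np.array(payload["X"]), np.array(payload["y"]))


def _grouped_splits(subjects: np.ndarray, n_splits: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic subject-grouped splits (subjects in sorted order)."""
    uniq = np.array(sorted(set(subjects)))
    chunks = np.array_split(uniq, n_splits)
    splits = []
    for chunk in chunks:
        test = np.isin(subjects, chunk)
        splits.append((~test, test))
    return splits


def select_k(
    X: np.ndarray,
    y: np.ndarray,
    subjects: np.ndarray,
    candidates: Sequence[int] = DEFAULT_K_GRID,
    n_inner: int = 3,
) -> int:
    """Choose k by an inner subject-grouped validation sweep.

    Every candidate is evaluated by macro F1 pooled over inner folds; the
    best wins, ties going to the smallest k. Candidates larger than the
    smallest inner training set are skipped.
    """
    subjects = np.asarray(subjects)
    uniq = sorted(set(subjects))
    if len(uniq) < 2:
        raise ValueError("inner validation needs at least 2 training subjects")
    n_inner = min(n_inner, len(uniq))
    splits = _grouped_splits(subjects, n_inner)
    classes = tuple(sorted(set(y)))
    min_train = min(int(tr.sum()) for tr, _ in splits)
    usable = [k for k in candidates if k <= min_train]
    if not usable:
        raise ValueError(f"no candidate k fits the inner training size {min_train}")
    best_k, best_f1 = None, -1.0
    for k in sorted(usable):
        cms = []
        for tr, te in splits:
            model = KNNModel(k, X[tr], y[tr])
            cms.append(confusion(y[te], model.predict(X[te]), classes))
        pooled = cms[0]
        for cm in cms[1:]:
            pooled = pooled + cm
        f1 = precision_recall_f1(pooled).macro_f1
        if f1 > best_f1:  # strict: ties keep the smaller k
            best_k, best_f1 = k, f1
    return int(best_k)


@dataclass
class SVMModel:
    """Linear SVM decision machine(s): one row of ``weights``/``biases``
    per binary machine (a single machine for two classes)."""

    classes: tuple[str, ...]
    weights: np.ndarray
    biases: np.ndarray
    C: float
    scheme: str
    support_vectors: np.ndarray
    _estimator: object | None = field(default=None, repr=False)

    def decision_values(self, Xq: np.ndarray) -> np.ndarray:
        Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
        return Xq @ self.weights.T + self.biases

    def predict(self, Xq: np.ndarray) -> np.ndarray:
        Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
        if self._estimator is not None:
            return np.asarray(self._estimator.predict(Xq))
        scores = self.decision_values(Xq)
        if len(self.classes) == 2:
            idx = (scores[:, 0] > 0).astype(int)
        else:
            idx = scores.argmax(axis=1)
        return np.array([self.classes[i] for i in idx])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "seatsense-svm/1",
            "classes": list(self.classes),
            "weights": self.weights.tolist(),
            "biases": self.biases.tolist(),
            "C": self.C,
            "scheme": self.scheme,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SVMModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "seatsense-svm/1":
            raise ValueError("not a seatsense SVM model file")
        return cls(
            tuple(payload["classes"]),
            np.array(payload["weights"]),
            np.array(payload["biases"]),
            payload["C"],
            payload["scheme"],
            support_vectors=np.empty((0,)),
        )


def svm_train(
    X: np.ndarray, y: np.ndarray, C: float = 1.0, scheme: str = "ovo", tol: float = 1e-3
) -> SVMModel:
    """Fit a linear soft-margin SVM on standardised features.

    ``scheme="ovo"`` (default) fits pairwise machines, which can isolate a
    class that lies between two others along a feature direction;
    ``"ovr"`` fits one machine per class against the rest. Binary problems always yield a
    single machine whose decision sign separates the two classes (positive
    side = lexicographically larger class, sklearn convention).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = tuple(sorted(set(y)))
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    if scheme == "ovr" and len(classes) > 2:
        est = OneVsRestClassifier(SVC(kernel="linear", C=C, tol=tol))
        est.fit(X, y)
        weights = np.vstack([e.coef_ for e in est.estimators_])
        biases = np.concatenate([e.intercept_ for e in est.estimators_])
        sv = np.vstack([e.support_vectors_ for e in est.estimators_])
    elif scheme in ("ovr", "ovo"):
        est = SVC(kernel="linear", C=C, tol=tol)
        est.fit(X, y)
        weights = est.coef_
        biases = est.intercept_
        sv = est.support_vectors_
    else:
        raise ValueError(f"unknown multiclass scheme {scheme!r}")
    return SVMModel(classes, weights, biases, C, scheme, sv, _estimator=est)


@dataclass
class FoldAssignment:
    """Mapping subject -> fold index; each subject tested exactly once."""

    fold_of: dict[str, int]
    n_folds: int

    def test_subjects(self, fold: int) -> set[str]:
        return {s for s, f in self.fold_of.items() if f == fold}

    def train_subjects(self, fold: int) -> set[str]:
        return {s for s, f in self.fold_of.items() if f != fold}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"n_folds": self.n_folds, "fold_of": self.fold_of}, indent=1)
        )


def make_subject_folds(
    subjects: Sequence[str], n_folds: int = 4, seed: int = 0
) -> FoldAssignment:
    """Seeded random partition of subjects into equal folds."""
    uniq = sorted(set(map(str, subjects)))
    if len(uniq) % n_folds:
        raise ValueError(f"{len(uniq)} subjects not divisible into {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    per = len(uniq) // n_folds
    fold_of = {uniq[idx]: int(pos // per) for pos, idx in enumerate(order)}
    return FoldAssignment(fold_of, n_folds)


def to_binary_labels(labels: Sequence[str]) -> np.ndarray:
    """Collapse the compensation patterns {TLF, TR, SE} to a single class
    ``C`` for the detection task (NC vs C)."""
    return np.array(["NC" if v == "NC" else "C" for v in labels])


def cross_validate(
    table: pd.DataFrame,
    classifier: str,
    folds: FoldAssignment,
    *,
    feature_cols: Sequence[str] = FEATURE_NAMES,
    label_col: str = "label",
    subject_col: str = "subject",
    class_order: Sequence[str] | None = None,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    C: float = 1.0,
    scheme: str = "ovo",
) -> EvaluationReport:
    """Subject-grouped cross-validation of one classifier on a feature table.

    Per fold: fit the standardiser and the model on training-subject rows
    only, predict the held-out subjects, and tally a confusion matrix.
    No test row ever influences training or standardisation.
    """
    if classifier not in ("knn", "svm"):
        raise ValueError(f"unknown classifier {classifier!r}")
    X_all = table[list(feature_cols)].to_numpy(dtype=float)
    y_all = table[label_col].to_numpy()
    subj_all = table[subject_col].astype(str).to_numpy()
    classes = tuple(class_order) if class_order else tuple(sorted(set(y_all)))
    fold_cms: list[ConfusionMatrix] = []
    fold_metrics = []
    params = []
    pred_rows: list[pd.DataFrame] = []
    for fold in range(folds.n_folds):
        test_subjects = folds.test_subjects(fold)
        te = np.isin(subj_all, sorted(test_subjects))
        tr = ~te
        if not te.any() or not tr.any():
            raise ValueError(f"fold {fold}: empty train or test split")
        missing = set(classes) - set(y_all[tr])
        if missing:
            raise ValueError(f"fold {fold}: training set lacks class(es) {sorted(missing)}")
        std = Standardizer.fit(X_all[tr], tuple(feature_cols))
        Xtr, Xte = std.transform(X_all[tr]), std.transform(X_all[te])
        if classifier == "knn":
            k = select_k(Xtr, y_all[tr], subj_all[tr], candidates=k_grid)
            model = KNNModel(k, Xtr, y_all[tr])
            params.append({"k": k})
        else:
            model = svm_train(Xtr, y_all[tr], C=C, scheme=scheme)
            params.append({"C": C, "scheme": scheme})
        pred = model.predict(Xte)
        cm = confusion(y_all[te], pred, classes)
        fold_cms.append(cm)
        fold_metrics.append(precision_recall_f1(cm))
        pred_rows.append(
            pd.DataFrame(
                {
                    "row": np.flatnonzero(te),
                    "subject": subj_all[te],
                    "fold": fold,
                    "true": y_all[te],
                    "pred": pred,
                }
            )
        )
    predictions = pd.concat(pred_rows, ignore_index=True)
    return EvaluationReport(classes, fold_cms, fold_metrics, params, predictions)
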