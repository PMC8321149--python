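"""Nearest-neighbor classification (L1) and holdout evaluation.

The classifier is deliberately minimal — 1-NN with the city-block distance —
so that evaluation isolates the contribution of the selected feature
subspace rather than classifier tuning.  Holdout accuracy is the rate of
well-classified test images.

Benchmark texture suites ship only train/test splits, so the embedded
selection step historically reuses the test subset as its validation subset.
That protocol is reproduced behind an explicit flag (the default), with a
logged warning about its optimistic bias; a proper three-way split mode is
available whenever a distinct validation subset exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .lbp import FeatureMatrix
from .selection import SelectionResult

logger = logging.getLogger(__name__)


def l1_distance(x: np.ndarray, y: np.ndarray) -> float:
    """City-block distance sum |x_i - y_i|."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.abs(x - y).sum())


def nn_predict(
    train_values: np.ndarray,
    train_labels: np.ndarray,
    queries: np.ndarray,
) -> np.ndarray:
    """1-NN/L1 labels for query rows; distance ties go to the lowest index."""
    train_values = np.atleast_2d(train_values)
    if train_values.shape[0] == 0:
        raise ValueError("empty training set")
    queries = np.atleast_2d(queries)
    dist = cdist(queries, train_values, metric="cityblock")
    return np.asarray(train_labels)[np.argmin(dist, axis=1)]


@dataclass
class EvaluationReport:
    """Holdout classification outcome on the test subset."""

    accuracy: float
    classes: list
    confusion: np.ndarray  # confusion[i, j]: true class i predicted as class j
    protocol: str  # "validation-equals-test" or "proper-split"
    n_features: int

    @property
    def per_class_accuracy(self) -> np.ndarray:
        totals = self.confusion.sum(axis=1)
        return np.divide(
            np.diag(self.confusion), np.where(totals > 0, totals, 1),
            where=True,
        )

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "per_class_accuracy": self.per_class_accuracy.tolist(),
            "protocol": self.protocol,
            "n_features": self.n_features,
        }

    def summary(self) -> str:
        lines = [
            f"protocol: {self.protocol}",
            f"features: {self.n_features}",
            f"accuracy: {self.accuracy:.4f}",
        ]
        for c, a in zip(self.classes, self.per_class_accuracy):
            lines.append(f"  class {c}: {a:.4f}")
        return "\n".join(lines)


def evaluate_holdout(
    train: FeatureMatrix,
    test: FeatureMatrix,
    selection: SelectionResult | None = None,
    validation_equals_test: bool = True,
) -> EvaluationReport:
    """Classify the test subset in the selected subspace and report accuracy."""
    if train.n_features != test.n_features:
        raise ValueError("train and test feature matrices disagree on columns")
    if selection is not None:
        cols = np.asarray(selection.selected_columns, dtype=np.intp)
        if cols.size and cols.max() >= train.n_features:
            raise ValueError("selection refers to columns outside the feature matrix")
    else:
        cols = np.arange(train.n_features, dtype=np.intp)
    if validation_equals_test:
        logger.warning(
            "validation subset equals test subset (benchmark-style protocol); "
            "reported accuracy is optimistically biased"
        )
    pred = nn_predict(train.values[:, cols], train.labels, test.values[:, cols])
    classes = sorted(set(np.asarray(train.labels).tolist())
                     | set(np.asarray(test.labels).tolist()))
    index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(test.labels, pred):
        confusion[index[t], index[p]] += 1
    accuracy = float(np.trace(confusion) / confusion.sum())
    return EvaluationReport(
        accuracy=accuracy,
        classes=classes,
        confusion=confusion,
        protocol="validation-equals-test" if validation_equals_test else "proper-split",
        n_features=int(cols.size),
    )
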