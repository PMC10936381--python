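"""Confusion-matrix comparison of two cell classifications on matched cells.

Two classification runs over the *same* segmentation yield one expected and
one predicted label per cell id. The confusion matrix cross-tabulates them
(rows = expected, columns = predicted, axis orders = first appearance), each
matrix element owns a retrievable selection of the exact cells it counted,
and the summary reports overall agreement plus per-class recall/precision.
Metrics with a zero denominator, and classes absent from one of the two label
sets, are reported as undefined (NaN), never coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_tables import PairedClassification, _first_appearance_order


@dataclass(frozen=True)
class ConfusionMatrix:
    expected_classes: list[str]
    predicted_classes: list[str]
    counts: np.ndarray
    total: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64).reshape(
            len(self.expected_classes), len(self.predicted_classes)
        )
        if counts.sum() != self.total:
            raise ValidationError("confusion counts must sum to total")
        object.__setattr__(self, "counts", counts)

    def count(self, expected: str, predicted: str) -> int:
        return int(
            self.counts[
                self.expected_classes.index(expected),
                self.predicted_classes.index(predicted),
            ]
        )


@dataclass(frozen=True)
class AgreementSummary:
    """Overall agreement fraction plus per-class recall and precision.

    ``recall``/``precision`` map class name -> value; NaN marks a class that
    is missing from the other axis or has a zero denominator.
    """

    agreement: float
    recall: dict[str, float]
    precision: dict[str, float]


def confusion_matrix(pairs: PairedClassification) -> ConfusionMatrix:
    """Cross-tabulate expected (rows) against predicted (columns) labels."""
    if len(pairs) == 0:
        raise ValidationError("cannot build a confusion matrix from zero cells")
    expected_classes = _first_appearance_order(pairs.expected)
    predicted_classes = _first_appearance_order(pairs.predicted)
    row = pd.Categorical(pairs.expected, categories=expected_classes).codes
    col = pd.Categorical(pairs.predicted, categories=predicted_classes).codes
    counts = np.zeros((len(expected_classes), len(predicted_classes)), dtype=np.int64)
    np.add.at(counts, (row, col), 1)
    return ConfusionMatrix(expected_classes, predicted_classes, counts, len(pairs))


def select_cells(
    pairs: PairedClassification, expected: str, predicted: str
) -> list[tuple[str, float, float]]:
    """The (cell_id, x, y) of exactly the cells in one confusion-matrix element.

    Cells come back in input order, ready for a spatial viewer.
    """
    if expected not in set(pairs.expected):
        raise ValidationError(f"unknown expected class: {expected!r}")
    if predicted not in set(pairs.predicted):
        raise ValidationError(f"unknown predicted class: {predicted!r}")
    mask = (pairs.expected == expected) & (pairs.predicted == predicted)
    return [
        (str(i), float(x), float(y))
        for i, x, y in zip(pairs.ids[mask], pairs.x[mask], pairs.y[mask])
    ]


def agreement_summary(matrix: ConfusionMatrix) -> AgreementSummary:
    """Overall agreement (sum of matched-label diagonal / total) and per-class metrics."""
    shared = [c for c in matrix.expected_classes if c in matrix.predicted_classes]
    diag = {c: matrix.count(c, c) for c in shared}
    agreement = sum(diag.values()) / matrix.total if matrix.total else np.nan

    union = _first_appearance_order(
        list(matrix.expected_classes) + list(matrix.predicted_classes)
    )
    recall: dict[str, float] = {}
    precision: dict[str, float] = {}
    for c in union:
        if c in diag:
            row_sum = int(matrix.counts[matrix.expected_classes.index(c)].sum())
            col_sum = int(matrix.counts[:, matrix.predicted_classes.index(c)].sum())
            recall[c] = diag[c] / row_sum if row_sum > 0 else np.nan
            precision[c] = diag[c] / col_sum if col_sum > 0 else np.nan
        else:
            recall[c] = np.nan
            precision[c] = np.nan
    return AgreementSummary(agreement=float(agreement), recall=recall, precision=precision)
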