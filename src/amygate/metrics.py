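"""Classification metrics: the precision-weighted F-beta score and friends.

The model-selection criterion of the gatekeeping system is the F_{1/10}
score,

    F_beta = (1 + beta^2) * P * R / (beta^2 * P + R),

with beta = 1/10, which weights precision ten times as heavily as recall.
Precision is taken for the APOE group's designated (majority) class.
"""

from __future__ import annotations

import dataclasses

import numpy as np

F110_BETA = 0.1


def _check_unit(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


def f_beta(precision: float, recall: float, beta: float = F110_BETA) -> float:
    """Precision-weighted F-beta score.

    ``beta`` is the relative contribution of recall over precision: beta < 1
    prioritizes precision. The degenerate case precision = recall = 0 is
    defined as 0.
    """
    _check_unit("precision", precision)
    _check_unit("recall", recall)
    if beta <= 0:
        raise ValueError(f"beta must be > 0, got {beta}")
    denom = beta * beta * precision + recall
    if denom == 0.0:
        return 0.0
    return (1.0 + beta * beta) * precision * recall / denom


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """Arithmetic mean of sensitivity and specificity."""
    _check_unit("sensitivity", sensitivity)
    _check_unit("specificity", specificity)
    return 0.5 * (sensitivity + specificity)


def precision_recall(y_true, y_pred, positive) -> tuple[float, float]:
    """Precision and recall of class ``positive``.

    Convention: precision is 0 when no positive predictions are made, recall
    is 0 when no positive truths exist, so downstream averages stay defined.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pred_pos = y_pred == positive
    true_pos = y_true == positive
    tp = int(np.sum(pred_pos & true_pos))
    precision = tp / pred_pos.sum() if pred_pos.sum() else 0.0
    recall = tp / true_pos.sum() if true_pos.sum() else 0.0
    return float(precision), float(recall)


@dataclasses.dataclass(frozen=True)
class MetricSet:
    """Designated-class test metrics of one evaluation setting."""

    precision: float
    recall: float
    f_1_10: float
    balanced_accuracy: float
    target_class: str
    n_test: int

    def __post_init__(self) -> None:
        expected = f_beta(self.precision, self.recall, F110_BETA)
        if abs(self.f_1_10 - expected) > 1e-12:
            raise ValueError(
                f"inconsistent MetricSet: f_1_10={self.f_1_10} but "
                f"F(P={self.precision}, R={self.recall}) = {expected}"
            )

    @classmethod
    def from_predictions(cls, y_true, y_pred, target_class, beta: float = F110_BETA) -> "MetricSet":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        p, r = precision_recall(y_true, y_pred, target_class)
        # sensitivity = recall of target class; specificity = recall of rest
        neg_true = y_true != target_class
        spec = (
            float(np.sum(neg_true & (y_pred != target_class)) / neg_true.sum())
            if neg_true.sum()
            else 0.0
        )
        return cls(
            precision=p,
            recall=r,
            f_1_10=f_beta(p, r, beta),
            balanced_accuracy=balanced_accuracy(r, spec),
            target_class=str(target_class),
            n_test=int(len(y_true)),
        )


def round_percent(x: float) -> int:
    """Round a proportion to the nearest full percent (half away from zero)."""
    import math

    return int(math.floor(abs(x) * 100.0 + 0.5)) * (1 if x >= 0 else -1)
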