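"""Confusion-matrix evaluation: accuracy, sensitivity, specificity.

The entries may be raw counts or percentages — the three rates are ratios,
so the two conventions give identical results.
"""

from __future__ import annotations

from dataclasses import dataclass

from .preprocess import ContractError


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FN/FP/TN as nonnegative counts or percentages."""

    tp: float
    fn: float
    fp: float
    tn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ContractError("confusion-matrix entries must be nonnegative")

    @property
    def total(self) -> float:
        return self.tp + self.fn + self.fp + self.tn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        """Counts from parallel 0/1 label sequences (1 = positive/infarcted)."""
        pairs = list(zip(y_true, y_pred))
        return cls(tp=sum(1 for t, p in pairs if t == 1 and p == 1),
                   fn=sum(1 for t, p in pairs if t == 1 and p == 0),
                   fp=sum(1 for t, p in pairs if t == 0 and p == 1),
                   tn=sum(1 for t, p in pairs if t == 0 and p == 0))


def compute_metrics(cm: ConfusionMatrix, ndigits: int | None = 1) -> dict[str, float]:
    """Accuracy, sensitivity and specificity in percent.

    accuracy   = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)

    Rounded half-up to ``ndigits`` decimals (default one, matching the usual
    reporting convention); pass ``ndigits=None`` for unrounded values.
    Sensitivity/specificity require at least one positive/negative instance.
    """
    if cm.total == 0:
        raise ContractError("confusion matrix is all zero")

    def pct(num: float, den: float) -> float:
        if den == 0:
            return float("nan")
        value = 100.0 * num / den
        if ndigits is None:
            return value
        scale = 10.0 ** ndigits
        return int(value * scale + 0.5) / scale  # round half up

    return {
        "accuracy": pct(cm.tp + cm.tn, cm.total),
        "sensitivity": pct(cm.tp, cm.tp + cm.fn),
        "specificity": pct(cm.tn, cm.tn + cm.fp),
    }
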