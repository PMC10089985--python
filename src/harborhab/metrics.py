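"""Binary presence/absence fit statistics.

The ten-statistic suite used to evaluate the species models, computed from
a 2x2 confusion table with presence as the positive class: accuracy, Cohen's
kappa, null accuracy (always predict the dominant class), an exact binomial
accuracy p-value, sensitivity, specificity, precision, negative predictive
value, F1 and balanced accuracy.  Ratios with zero denominators are
reported as missing (NaN), never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.n == 0:
            raise ValueError("confusion table must contain at least one case")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class FitMetrics:
    accuracy: float
    kappa: float
    accuracy_null: float
    accuracy_p: float
    sensitivity: float
    specificity: float
    precision: float
    npv: float
    f1: float
    balance: float

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def confusion_counts(truth, predicted) -> ConfusionCounts:
    """Cross-tabulate truth vs prediction (presence = positive class = 1)."""
    t = np.asarray(truth).astype(int)
    p = np.asarray(predicted).astype(int)
    if t.shape != p.shape:
        raise ValueError("truth and predicted must have the same length")
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def accuracy_p_value(correct_count: int, n: int, accuracy_null: float) -> float:
    """One-sided exact binomial tail P(X >= correct_count), X ~ Bin(n, null).

    The probability of observing at least the achieved number of correct
    predictions if the classifier were no better than always predicting the
    dominant class.
    """
    if not 0 <= correct_count <= n:
        raise ValueError("correct_count must lie in [0, n]")
    return float(stats.binom.sf(correct_count - 1, n, accuracy_null))


def compute_fit_metrics(counts: ConfusionCounts) -> FitMetrics:
    """The ten fit statistics from a confusion table.

    kappa = (accuracy - p_e) / (1 - p_e) with p_e the chance agreement from
    the table's marginals; F1 is the harmonic mean of precision and
    sensitivity; balance is the mean of sensitivity and specificity.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    n = counts.n
    pos, neg = tp + fn, tn + fp
    accuracy = (tp + tn) / n
    sensitivity = _ratio(tp, pos)
    specificity = _ratio(tn, neg)
    precision = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    accuracy_null = max(pos, neg) / n
    pe = (pos * (tp + fp) + neg * (fn + tn)) / (n * n)
    kappa = (accuracy - pe) / (1 - pe) if pe < 1 else float("nan")
    f1 = (2 * precision * sensitivity / (precision + sensitivity)
          if precision + sensitivity > 0 else float("nan"))
    balance = (sensitivity + specificity) / 2
    return FitMetrics(
        accuracy=accuracy, kappa=kappa, accuracy_null=accuracy_null,
        accuracy_p=accuracy_p_value(tp + tn, n, accuracy_null),
        sensitivity=sensitivity, specificity=specificity,
        precision=precision, npv=npv, f1=f1, balance=balance,
    )


def confusion_from_rates(sensitivity: float, specificity: float,
                         accuracy_null: float, n: int = 10_000) -> ConfusionCounts:
    """Reconstruct an (integer) confusion table from reported rates.

    Assumes absence is the dominant class (the zero-inflated presence
    setting), so prevalence = 1 - accuracy_null.  Used for worked examples
    that recompute the remaining fit statistics from a published table.
    """
    neg = round(accuracy_null * n)
    pos = n - neg
    tp = round(sensitivity * pos)
    tn = round(specificity * neg)
    return ConfusionCounts(tp=tp, fp=neg - tn, tn=tn, fn=pos - tp)
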