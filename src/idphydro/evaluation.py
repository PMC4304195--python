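"""Imbalanced-data evaluation: confusion counts, the metric suite, ROC AUC.

Disorder prediction corpora are heavily skewed toward structured
proteins, so plain accuracy is uninformative (predicting "ordered"
everywhere already scores ~0.84 on a 16/84 split).  This module
implements the standard remedy suite with disordered as the positive
class:

* sensitivity (recall of disorder), specificity (recall of order) and
  their mean, the balanced accuracy;
* PPV (precision) and NPV, which expose over-prediction of either class;
* the F-score (harmonic mean of precision and recall) and the Matthews
  correlation coefficient, both single-number summaries robust to
  imbalance;
* ROC AUC, computed by the rank-sum (Mann-Whitney) identity with ties
  credited 0.5.

Any metric whose denominator is zero is reported as ``None`` (an
explicit undefined marker) rather than silently coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .io import DISORDERED, LABELS

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "metrics",
    "roc_auc",
    "aggregate_reports",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN with disordered as the positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.TN + other.TN,
            self.FP + other.FP, self.FN + other.FN,
        )


@dataclass(frozen=True)
class MetricsReport:
    """The full metric suite; ``None`` marks an undefined (0/0) value."""

    acc: float | None
    sensitivity: float | None
    specificity: float | None
    balanced_acc: float | None
    ppv: float | None
    npv: float | None
    f: float | None
    mcc: float | None
    auc: float | None = None

    def as_dict(self) -> dict:
        return {
            "acc": self.acc,
            "sens": self.sensitivity,
            "spec": self.specificity,
            "bal_acc": self.balanced_acc,
            "ppv": self.ppv,
            "npv": self.npv,
            "f": self.f,
            "mcc": self.mcc,
            "auc": self.auc,
        }


def confusion(
    predicted: Sequence[str], true: Sequence[str]
) -> ConfusionCounts:
    """Tally a confusion matrix from parallel label sequences."""
    if len(predicted) != len(true):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions vs "
            f"{len(true)} truths"
        )
    if len(true) == 0:
        raise ValueError("cannot build a confusion matrix from no examples")
    tp = tn = fp = fn = 0
    for p, t in zip(predicted, true):
        if p not in LABELS or t not in LABELS:
            raise ValueError(f"unknown label in pair ({p!r}, {t!r})")
        if t == DISORDERED:
            if p == DISORDERED:
                tp += 1
            else:
                fn += 1
        else:
            if p == DISORDERED:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Compute the full suite from confusion counts (AUC left unset).

    Each metric follows its textbook definition; MCC's denominator is
    the square root of the product of the four pairwise sums.  A zero
    denominator yields ``None``, never a silent 0.
    """
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    if counts.total == 0:
        raise ValueError("all-zero confusion counts")
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    bal = (sens + spec) / 2 if sens is not None and spec is not None else None
    if ppv is None or sens is None or ppv + sens == 0:
        f = None
    else:
        f = 2 * ppv * sens / (ppv + sens)
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom2) if denom2 > 0 else None
    return MetricsReport(
        acc=_ratio(tp + tn, counts.total),
        sensitivity=sens,
        specificity=spec,
        balanced_acc=bal,
        ppv=ppv,
        npv=npv,
        f=f,
        mcc=mcc,
    )


def roc_auc(scores: Sequence[float], labels: Sequence[str]) -> float:
    """Area under the ROC curve by the Mann-Whitney rank identity.

    ``scores`` must be oriented so that larger means more disordered.
    Equals the probability that a uniformly chosen disordered example
    outscores a uniformly chosen ordered one, with ties counted 0.5 —
    identical to the trapezoidal area under the empirical ROC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(scores) != len(labels):
        raise ValueError("scores and labels must have equal length")
    pos = labels == DISORDERED
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)  # average ranks handle ties as 0.5 credit
    rank_sum_pos = float(ranks[pos].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def aggregate_reports(
    reports: Sequence[MetricsReport],
) -> dict[str, dict[str, float | None | int]]:
    """Fold-wise mean and sample standard deviation per metric.

    Undefined (``None``) entries are skipped and their count reported;
    a metric undefined in every fold aggregates to ``None``.  Standard
    deviation uses the n-1 convention and is ``None`` for a single
    defined value.
    """
    out: dict[str, dict] = {}
    keys = reports[0].as_dict().keys() if reports else ()
    for key in keys:
        vals = [r.as_dict()[key] for r in reports]
        defined = [v for v in vals if v is not None]
        n_undef = len(vals) - len(defined)
        if not defined:
            out[key] = {"mean": None, "std": None, "n_undefined": n_undef}
        else:
            arr = np.array(defined, dtype=float)
            std = float(arr.std(ddof=1)) if len(arr) > 1 else None
            out[key] = {
                "mean": float(arr.mean()),
                "std": std,
                "n_undefined": n_undef,
            }
    return out
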