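"""Diagnostic validation of a difficulty score against the operative outcome.

Confusion matrices and the standard 2x2 test metrics (sensitivity,
specificity, PPV, NPV, accuracy, prevalence) with Wilson 95% confidence
intervals; ROC curves over integer score thresholds with trapezoidal AUC;
and the conventional five-level AUC interpretation scale (>=0.9 excellent,
0.8-0.9 good, 0.7-0.8 fair, 0.6-0.7 poor, 0.5-0.6 fail).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .types import ValidationError

__all__ = [
    "ConfusionMatrix",
    "DiagnosticMetrics",
    "ROCCurve",
    "confusion",
    "metrics",
    "roc",
    "auc_band",
]

_LABELS = ("easy", "difficult")


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 cross-tabulation of predicted vs actual difficulty.

    ``difficult`` is the positive class: ``tp`` counts operations predicted
    difficult that were difficult, ``tn`` those predicted easy that were
    easy.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Diagnostic test proportions with Wilson 95% intervals.

    A metric whose denominator is zero is reported as NaN and listed in
    ``undefined`` rather than silently set to 0.
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    prevalence: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    undefined: frozenset[str] = frozenset()


@dataclass(frozen=True)
class ROCCurve:
    """ROC curve over score thresholds, higher score = more likely difficult.

    ``thresholds[i]`` is the cut-off "score >= t" generating
    ``(fpr[i], tpr[i])``; the first threshold is +inf so the curve starts at
    (0, 0) and the last is the minimum observed score so it ends at (1, 1).
    ``auc`` is the trapezoidal area.
    """

    thresholds: tuple[float, ...]
    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    auc: float

    @property
    def points(self) -> tuple[tuple[float, float], ...]:
        return tuple(zip(self.fpr, self.tpr))


def _check_labels(name: str, labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.size == 0:
        raise ValidationError(f"{name} is empty")
    bad = ~np.isin(arr, _LABELS)
    if bad.any():
        i = int(np.argmax(bad))
        raise ValidationError(f"{name}[{i}] = {arr[i]!r}; labels must be easy/difficult")
    return arr == "difficult"


def confusion(predictions, outcomes) -> ConfusionMatrix:
    """Cross-tabulate easy/difficult predictions against outcomes."""
    pred = _check_labels("predictions", predictions)
    out = _check_labels("outcomes", outcomes)
    if pred.shape != out.shape:
        raise ValidationError(
            f"length mismatch: {pred.size} predictions vs {out.size} outcomes"
        )
    return ConfusionMatrix(
        tp=int(np.sum(pred & out)),
        fp=int(np.sum(pred & ~out)),
        fn=int(np.sum(~pred & out)),
        tn=int(np.sum(~pred & ~out)),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def metrics(cm: ConfusionMatrix, ci_alpha: float = 0.05) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV, accuracy and prevalence from a
    confusion matrix, each with a Wilson score interval at level
    ``1 - ci_alpha``.
    """
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    parts = {
        "sensitivity": (cm.tp, cm.tp + cm.fn),
        "specificity": (cm.tn, cm.tn + cm.fp),
        "ppv": (cm.tp, cm.tp + cm.fp),
        "npv": (cm.tn, cm.tn + cm.fn),
        "accuracy": (cm.tp + cm.tn, cm.total),
        "prevalence": (cm.tp + cm.fn, cm.total),
    }
    values: dict[str, float] = {}
    cis: dict[str, tuple[float, float]] = {}
    undefined: set[str] = set()
    for name, (num, den) in parts.items():
        values[name] = _ratio(num, den)
        if den > 0:
            lo, hi = proportion_confint(num, den, alpha=ci_alpha, method="wilson")
            cis[name] = (float(lo), float(hi))
        else:
            undefined.add(name)
            cis[name] = (math.nan, math.nan)
    return DiagnosticMetrics(ci=cis, undefined=frozenset(undefined), **values)


def roc(scores, outcomes) -> ROCCurve:
    """ROC curve of an integer-valued score against easy/difficult outcomes.

    One operating point per distinct observed score, using the rule
    "predict difficult when score >= t", plus a +inf sentinel so the curve
    includes (0, 0). The AUC is the trapezoidal area, which for this step
    curve equals the Mann-Whitney concordance probability with ties counted
    one half.
    """
    s = np.asarray(scores, dtype=float)
    y = _check_labels("outcomes", outcomes)
    if s.size != y.size:
        raise ValidationError(f"length mismatch: {s.size} scores vs {y.size} outcomes")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("outcomes contain a single class; AUC is undefined")
    cuts = np.concatenate([[np.inf], np.unique(s)[::-1]])
    tpr = [float(np.sum((s >= t) & y)) / n_pos for t in cuts]
    fpr = [float(np.sum((s >= t) & ~y)) / n_neg for t in cuts]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(
        thresholds=tuple(float(t) for t in cuts),
        fpr=tuple(fpr),
        tpr=tuple(tpr),
        auc=auc,
    )


_AUC_BANDS = (
    (0.9, "Excellent"),
    (0.8, "Good"),
    (0.7, "Fair"),
    (0.6, "Poor"),
    (0.0, "Fail"),
)


def auc_band(auc: float) -> str:
    """Five-level interpretation label for an AUC in [0, 1].

    An AUC below 0.5 means the score discriminates worse than chance; it is
    labelled Fail with a warning suggesting the orientation be checked.
    """
    if not 0.0 <= auc <= 1.0:
        raise ValidationError(f"AUC must lie in [0, 1], got {auc}")
    if auc < 0.5:
        warnings.warn(
            f"AUC {auc:.3f} is below 0.5: worse than chance; "
            "check the score orientation",
            stacklevel=2,
        )
    for cut, label in _AUC_BANDS:
        if auc >= cut:
            return label
    return "Fail"
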