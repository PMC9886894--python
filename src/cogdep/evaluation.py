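"""Confusion-matrix metrics for depression detection, in two modes.

``standard`` mode uses the universal definitions: recall (sensitivity)
TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP) and F1 as the
harmonic mean of precision and recall.

``paper_literal`` mode reproduces, verbatim, a nonstandard printed variant
sometimes seen in the applied literature, in which the sensitivity formula
TP/(TP+FN) is reported under the name "specificity", "precision" is
computed as TP/(TP+TN), and F1 is the harmonic mean of those two
quantities.  The two modes disagree in general; every report is stamped
with the mode that produced it so numbers are never silently reinterpreted.

The positive class is the depressed cohort throughout.  Undefined ratios
(zero denominators) are reported as absent (``None``), never as 0.
"""

from __future__ import annotations

from typing import Literal, Optional, Sequence

from pydantic import BaseModel

from .taxonomy import DistortionCategory

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "confusion",
    "metrics",
    "post_level_report",
    "PostLevelReport",
]


class ConfusionMatrix(BaseModel):
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


class MetricReport(BaseModel):
    mode: Literal["standard", "paper_literal"]
    recall: Optional[float] = None       # a.k.a. sensitivity
    specificity: Optional[float] = None
    precision: Optional[float] = None
    f1: Optional[float] = None
    accuracy: Optional[float] = None

    def as_percent(self, ndigits: int = 2) -> dict:
        """Values scaled to percentages with fixed decimals (report style)."""
        out: dict = {"mode": self.mode}
        for k in ("recall", "specificity", "precision", "f1", "accuracy"):
            v = getattr(self, k)
            out[k] = None if v is None else round(100.0 * v, ndigits)
        return out


def confusion(gold: Sequence[int], predicted: Sequence[int]) -> ConfusionMatrix:
    """Count TP/TN/FP/FN with positive = depressed (label 1)."""
    if len(gold) != len(predicted):
        raise ValueError(
            f"length mismatch: {len(gold)} gold vs {len(predicted)} predicted"
        )
    cm = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    for g, p in zip(gold, predicted):
        if g not in (0, 1) or p not in (0, 1):
            raise ValueError("labels must be binary 0/1")
        if g == 1:
            cm["tp" if p == 1 else "fn"] += 1
        else:
            cm["fp" if p == 1 else "tn"] += 1
    return ConfusionMatrix(**cm)


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def _harmonic(a: Optional[float], b: Optional[float]) -> Optional[float]:
    if a is None or b is None or a + b == 0:
        return None
    return 2 * a * b / (a + b)


def metrics(
    cm: ConfusionMatrix, mode: Literal["standard", "paper_literal"] = "standard"
) -> MetricReport:
    accuracy = _ratio(cm.tp + cm.tn, cm.total)
    if mode == "standard":
        recall = _ratio(cm.tp, cm.tp + cm.fn)
        specificity = _ratio(cm.tn, cm.tn + cm.fp)
        precision = _ratio(cm.tp, cm.tp + cm.fp)
        f1 = _harmonic(precision, recall)
        return MetricReport(mode=mode, recall=recall, specificity=specificity,
                            precision=precision, f1=f1, accuracy=accuracy)
    if mode == "paper_literal":
        # printed formulas applied verbatim: "specificity" is TP/(TP+FN),
        # "precision" is TP/(TP+TN); F1 harmonic-means those two.
        specificity = _ratio(cm.tp, cm.tp + cm.fn)
        precision = _ratio(cm.tp, cm.tp + cm.tn)
        f1 = _harmonic(specificity, precision)
        return MetricReport(mode=mode, recall=None, specificity=specificity,
                            precision=precision, f1=f1, accuracy=accuracy)
    raise ValueError(f"unknown mode {mode!r}")


class PostLevelReport(BaseModel):
    accuracy: float
    per_category: dict[str, dict[str, Optional[float]]]


def post_level_report(
    gold: Sequence[DistortionCategory], predicted: Sequence[DistortionCategory]
) -> PostLevelReport:
    """One-vs-rest precision/recall per category plus overall accuracy."""
    if len(gold) != len(predicted):
        raise ValueError("length mismatch between gold and predicted labels")
    for lab in list(gold) + list(predicted):
        if not isinstance(lab, DistortionCategory):
            raise ValueError(f"unknown category {lab!r}")
    correct = sum(1 for g, p in zip(gold, predicted) if g is p)
    per: dict[str, dict[str, Optional[float]]] = {}
    for cat in DistortionCategory:
        tp = sum(1 for g, p in zip(gold, predicted) if g is cat and p is cat)
        fn = sum(1 for g, p in zip(gold, predicted) if g is cat and p is not cat)
        fp = sum(1 for g, p in zip(gold, predicted) if g is not cat and p is cat)
        per[cat.code] = {
            "precision": _ratio(tp, tp + fp),
            "recall": _ratio(tp, tp + fn),
            "support": float(tp + fn),
        }
    return PostLevelReport(
        accuracy=correct / len(gold) if gold else 0.0, per_category=per
    )
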