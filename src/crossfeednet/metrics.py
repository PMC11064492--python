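"""Two-class evaluation: confusion counts, scalar panels, ROC and PR curves.

Counts are pooled over cross-validation folds before metrics are computed
(per-fold macro-averaging is available behind a flag).  With cross-feeding
(cf) and competition (co) as the two classes, the four pooled counts are

* ``tp_co`` — competition examples classified as competition,
* ``fn_co`` — competition examples classified as cross-feeding,
* ``fn_cf`` — cross-feeding examples classified as competition,
* ``tp_cf`` — cross-feeding examples classified as cross-feeding,

from which precision/recall/F1 for either target class, accuracy and balanced
accuracy all derive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_curve

from ._exceptions import ValidationError
from .encoding import COMPETITION, CROSS_FEEDING

__all__ = [
    "ConfusionCounts",
    "MetricPanel",
    "CurveResult",
    "panel_from_counts",
    "random_baseline_precision",
    "roc_curve_and_auc",
    "pr_curve_and_auc",
    "display_round",
]


def display_round(x: float, decimals: int = 2) -> str:
    """Round half-up to ``decimals`` and trim trailing zeros (0.896 -> "0.9")."""
    q = Decimal(1).scaleb(-decimals)
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    s = format(d.normalize(), "f")
    return "0" if s == "-0" else s


@dataclass(frozen=True)
class ConfusionCounts:
    """Pooled two-class confusion counts."""

    tp_co: int
    fn_co: int
    fn_cf: int
    tp_cf: int

    def __post_init__(self):
        for name in ("tp_co", "fn_co", "fn_cf", "tp_cf"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def n_competition(self) -> int:
        return self.tp_co + self.fn_co

    @property
    def n_cross_feeding(self) -> int:
        return self.fn_cf + self.tp_cf

    @property
    def total(self) -> int:
        return self.n_competition + self.n_cross_feeding

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp_co + other.tp_co,
            self.fn_co + other.fn_co,
            self.fn_cf + other.fn_cf,
            self.tp_cf + other.tp_cf,
        )

    @classmethod
    def from_labels(cls, true: Sequence[str], predicted: Sequence[str]) -> "ConfusionCounts":
        true = np.asarray(true, dtype=object)
        predicted = np.asarray(predicted, dtype=object)
        if true.shape != predicted.shape:
            raise ValidationError("true/predicted label arrays differ in length")
        return cls(
            tp_co=int(((true == COMPETITION) & (predicted == COMPETITION)).sum()),
            fn_co=int(((true == COMPETITION) & (predicted == CROSS_FEEDING)).sum()),
            fn_cf=int(((true == CROSS_FEEDING) & (predicted == COMPETITION)).sum()),
            tp_cf=int(((true == CROSS_FEEDING) & (predicted == CROSS_FEEDING)).sum()),
        )

    def to_json(self) -> dict:
        return {"tp_co": self.tp_co, "fn_co": self.fn_co,
                "fn_cf": self.fn_cf, "tp_cf": self.tp_cf}


@dataclass
class MetricPanel:
    """Scalar metrics for both target classes, full precision + display strings."""

    precision_co: float
    recall_co: float
    f1_co: float
    precision_cf: float
    recall_cf: float
    f1_cf: float
    accuracy: float
    balanced_accuracy: float
    zero_division_flags: list[str] = field(default_factory=list)

    _FIELDS = (
        "precision_co", "recall_co", "f1_co",
        "precision_cf", "recall_cf", "f1_cf",
        "accuracy", "balanced_accuracy",
    )

    def display(self) -> dict[str, str]:
        """Two-decimal, half-up, trailing-zero-trimmed strings for reporting."""
        return {name: display_round(getattr(self, name)) for name in self._FIELDS}

    def to_json(self) -> dict:
        out = {name: float(getattr(self, name)) for name in self._FIELDS}
        out["display"] = self.display()
        if self.zero_division_flags:
            out["zero_division_flags"] = list(self.zero_division_flags)
        return out


def _safe_div(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def panel_from_counts(c: ConfusionCounts) -> MetricPanel:
    """All scalar metrics from pooled confusion counts.

    Precision for a target class divides by the number of examples *predicted*
    as that class (e.g. ``tp_co + fn_cf`` for competition); recall divides by
    the class total.  A zero denominator yields 0 with a flag rather than NaN.
    """
    if c.total == 0:
        raise ValidationError("all confusion counts are zero")
    flags: list[str] = []
    p_co = _safe_div(c.tp_co, c.tp_co + c.fn_cf, "precision_co", flags)
    r_co = _safe_div(c.tp_co, c.n_competition, "recall_co", flags)
    f1_co = _safe_div(2 * p_co * r_co, p_co + r_co, "f1_co", flags)
    p_cf = _safe_div(c.tp_cf, c.tp_cf + c.fn_co, "precision_cf", flags)
    r_cf = _safe_div(c.tp_cf, c.n_cross_feeding, "recall_cf", flags)
    f1_cf = _safe_div(2 * p_cf * r_cf, p_cf + r_cf, "f1_cf", flags)
    accuracy = (c.tp_co + c.tp_cf) / c.total
    balanced = (r_co + r_cf) / 2
    return MetricPanel(p_co, r_co, f1_co, p_cf, r_cf, f1_cf, accuracy, balanced, flags)


def macro_average_panels(panels: Iterable[MetricPanel]) -> MetricPanel:
    """Unweighted mean of per-fold panels (alternative to pooled counts)."""
    panels = list(panels)
    if not panels:
        raise ValidationError("no panels to average")
    values = {
        name: float(np.mean([getattr(p, name) for p in panels]))
        for name in MetricPanel._FIELDS
    }
    flags = sorted({f for p in panels for f in p.zero_division_flags})
    return MetricPanel(zero_division_flags=flags, **values)


def random_baseline_precision(class_counts: Mapping[str, int]) -> dict[str, float]:
    """Precision of a label-agnostic random predictor: the class prevalence.

    A predictor that guesses labels independently of the input has, for every
    target class, an expected precision equal to that class's prevalence.
    """
    total = sum(class_counts.values())
    if total <= 0:
        raise ValidationError("class counts must sum to a positive total")
    return {label: count / total for label, count in class_counts.items()}


@dataclass
class CurveResult:
    """A threshold-sweep curve (ROC or PR) for one target class, plus its area."""

    target: str
    kind: str               # "roc" or "pr"
    x: np.ndarray           # fpr (roc) or recall (pr)
    y: np.ndarray           # tpr (roc) or precision (pr)
    thresholds: np.ndarray
    area: float

    def to_json(self) -> dict:
        return {"target": self.target, "kind": self.kind, "area": float(self.area),
                "area_display": display_round(self.area)}


def _target_scores(
    true_labels: Sequence[str], scores_cf: Sequence[float], target: str
) -> tuple[np.ndarray, np.ndarray]:
    true_labels = np.asarray(true_labels, dtype=object)
    scores_cf = np.asarray(scores_cf, dtype=float)
    if target not in (CROSS_FEEDING, COMPETITION):
        raise ValidationError(f"unknown target class {target!r}")
    y = (true_labels == target).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValidationError(f"need both classes present to build a curve for {target}")
    s = scores_cf if target == CROSS_FEEDING else 1.0 - scores_cf
    return y, s


def roc_curve_and_auc(
    true_labels: Sequence[str], scores_cf: Sequence[float], target: str = COMPETITION
) -> CurveResult:
    """ROC curve and area (trapezoidal rule == Mann-Whitney statistic).

    ``scores_cf`` is the probability-of-cross-feeding score; the competition
    curve uses its complement.
    """
    y, s = _target_scores(true_labels, scores_cf, target)
    fpr, tpr, thr = roc_curve(y, s)
    area = float(np.trapezoid(tpr, fpr))
    return CurveResult(target, "roc", fpr, tpr, thr, area)


def pr_curve_and_auc(
    true_labels: Sequence[str],
    scores_cf: Sequence[float],
    target: str = COMPETITION,
    interpolation: str = "step",
) -> CurveResult:
    """Precision-recall curve and area.

    ``interpolation="step"`` (default) is the average-precision convention
    sum((R_i - R_{i-1}) * P_i); ``"trapezoid"`` linearly interpolates, which
    is known to be optimistic and is provided only for comparison.
    """
    y, s = _target_scores(true_labels, scores_cf, target)
    precision, recall, thr = precision_recall_curve(y, s)
    # sklearn returns the sweep with recall decreasing, ending at (0, 1)
    if interpolation == "step":
        area = float(-np.sum(np.diff(recall) * precision[:-1]))
    elif interpolation == "trapezoid":
        area = float(-np.trapezoid(precision, recall))
    else:
        raise ValidationError(f"unknown PR interpolation {interpolation!r}")
    return CurveResult(target, "pr", recall, precision, thr, area)


def metric_report(
    model: str,
    counts: ConfusionCounts,
    panel: Optional[MetricPanel] = None,
    true_labels: Optional[Sequence[str]] = None,
    scores_cf: Optional[Sequence[float]] = None,
) -> dict:
    """Assemble the JSON metric report for one classifier run."""
    panel = panel or panel_from_counts(counts)
    report = {"model": model, "counts": counts.to_json(), "panel": panel.to_json()}
    if true_labels is not None and scores_cf is not None:
        report["roc"] = {
            "co": roc_curve_and_auc(true_labels, scores_cf, COMPETITION).to_json(),
            "cf": roc_curve_and_auc(true_labels, scores_cf, CROSS_FEEDING).to_json(),
        }
        report["pr"] = {
            "co": pr_curve_and_auc(true_labels, scores_cf, COMPETITION).to_json(),
            "cf": pr_curve_and_auc(true_labels, scores_cf, CROSS_FEEDING).to_json(),
        }
    return report
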