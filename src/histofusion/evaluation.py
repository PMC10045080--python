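"""Confusion-matrix evaluation: per-class one-vs-rest metrics and ROC/AUC.

Every classifier in the pipeline is scored the same way: a 5 x 5
confusion matrix (rows = true class, columns = predicted), reduced
one-vs-rest per class to TP/FN/FP/TN, from which sensitivity, precision,
accuracy and specificity are computed as percentages, plus a one-vs-rest
ROC AUC from the score matrix.  The "macro average" of a metric is the
unweighted mean over the five classes.  Ratios with a zero denominator
(0/0) are reported as absent (None), never coerced to 0 or 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy.stats import rankdata

from histofusion.types import DEFAULT_CLASS_NAMES

METRIC_NAMES = ("sensitivity", "precision", "accuracy", "specificity", "auc")


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # rows = true class, columns = predicted class
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square and match class_names")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, k: int) -> tuple[int, int, int, int]:
        """(TP, FN, FP, TN) for class index k."""
        tp = int(self.counts[k, k])
        fn = int(self.counts[k].sum()) - tp
        fp = int(self.counts[:, k].sum()) - tp
        tn = self.total - tp - fn - fp
        return tp, fn, fp, tn


@dataclass
class MetricsReport:
    """Per-class metrics (percent) and their macro averages.

    ``per_class[metric]`` is a list aligned with ``class_names``; entries
    are ``None`` where the metric is undefined (0/0).
    """

    class_names: tuple[str, ...]
    per_class: dict = field(default_factory=dict)
    macro: dict = field(default_factory=dict)

    def rounded(self, decimals: int = 2) -> "MetricsReport":
        """Display copy with half-up rounding, matching report precision."""
        def r(v):
            if v is None:
                return None
            q = Decimal(1).scaleb(-decimals)
            return float(Decimal(repr(float(v))).quantize(q, rounding=ROUND_HALF_UP))
        return MetricsReport(
            class_names=self.class_names,
            per_class={m: [r(v) for v in vals] for m, vals in self.per_class.items()},
            macro={m: r(v) for m, v in self.macro.items()},
        )


def confusion(true_labels, predicted_labels,
              class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES) -> ConfusionMatrix:
    """counts[i][j] = number of samples with true class i predicted as j.

    Labels may be class names or integer indices into ``class_names``.
    """
    index = {name: i for i, name in enumerate(class_names)}

    def as_index(x):
        if isinstance(x, str):
            if x not in index:
                raise ValueError(f"unknown label {x!r}")
            return index[x]
        xi = int(x)
        if not 0 <= xi < len(class_names):
            raise ValueError(f"label index {xi} out of range")
        return xi

    t = [as_index(x) for x in true_labels]
    p = [as_index(x) for x in predicted_labels]
    if len(t) != len(p):
        raise ValueError("label sequences differ in length")
    counts = np.zeros((len(class_names), len(class_names)), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts=counts, class_names=class_names)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def per_class_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Sensitivity, precision, accuracy, specificity per class (one-vs-rest), percent.

    sensitivity = TP/(TP+FN), precision = TP/(TP+FP),
    accuracy = (TP+TN)/total, specificity = TN/(TN+FP), each x 100.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    report = MetricsReport(class_names=cm.class_names)
    per: dict[str, list] = {m: [] for m in ("sensitivity", "precision", "accuracy",
                                            "specificity")}
    for k in range(len(cm.class_names)):
        tp, fn, fp, tn = cm.one_vs_rest(k)
        per["sensitivity"].append(_ratio(tp, tp + fn))
        per["precision"].append(_ratio(tp, tp + fp))
        per["accuracy"].append(_ratio(tp + tn, cm.total))
        per["specificity"].append(_ratio(tn, tn + fp))
    report.per_class = per
    report.macro = {m: (macro_average(v) if all(x is not None for x in v) else None)
                    for m, v in per.items()}
    return report


def binary_auc(scores: np.ndarray, positives: np.ndarray) -> float:
    """One-vs-rest AUC as the Mann-Whitney pair statistic with half tie credit.

    Equivalent to trapezoidal integration of the threshold-sweep ROC
    curve.  Computed from midranks, so ties contribute 1/2 per pair.
    """
    scores = np.asarray(scores, dtype=np.float64)
    pos = np.asarray(positives, dtype=bool)
    n_pos = int(pos.sum())
    n_neg = pos.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: a class is absent")
    ranks = rankdata(scores)  # midranks
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc(scores: np.ndarray, true_labels,
            class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES) -> list[float | None]:
    """Per-class one-vs-rest AUC (percent) from an n x n_classes score matrix.

    Classes absent from ``true_labels`` get ``None``.
    """
    S = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(S)):
        raise ValueError("scores must be finite")
    labels = np.asarray([class_names.index(x) if isinstance(x, str) else int(x)
                         for x in true_labels])
    out: list[float | None] = []
    for k in range(len(class_names)):
        pos = labels == k
        if pos.sum() == 0 or pos.sum() == labels.size:
            out.append(None)
        else:
            out.append(100.0 * binary_auc(S[:, k], pos))
    return out


def roc_curve_points(scores: np.ndarray, positives: np.ndarray):
    """(FPR, TPR) points of the threshold-sweep ROC curve, for reports/plots."""
    scores = np.asarray(scores, dtype=np.float64)
    pos = np.asarray(positives, dtype=bool)
    order = np.argsort(-scores, kind="stable")
    s, p = scores[order], pos[order]
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    tps = np.cumsum(p)[distinct]
    fps = np.cumsum(~p)[distinct]
    tpr = np.r_[0.0, tps / max(1, p.sum())]
    fpr = np.r_[0.0, fps / max(1, (~p).sum())]
    return fpr, tpr


def macro_average(per_class_values) -> float:
    """Unweighted arithmetic mean of per-class metric values."""
    vals = list(per_class_values)
    if any(v is None for v in vals):
        raise ValueError("missing per-class value")
    return float(np.mean([float(v) for v in vals]))


def round_half_up(value: float, decimals: int = 2) -> float:
    """Display rounding used in reports (half-up at 2 decimals)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def evaluate_predictions(true_labels, predicted_labels, scores=None,
                         class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES,
                         ) -> tuple[ConfusionMatrix, MetricsReport]:
    """Full evaluation: confusion matrix + metrics report (AUC when scores given)."""
    cm = confusion(true_labels, predicted_labels, class_names)
    report = per_class_metrics(cm)
    if scores is not None:
        aucs = roc_auc(scores, true_labels, class_names)
        report.per_class["auc"] = aucs
        report.macro["auc"] = (macro_average(aucs)
                               if all(a is not None for a in aucs) else None)
    return cm, report
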