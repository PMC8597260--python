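"""Confusion-matrix evaluation battery for binary and ternary classifiers.

Mirrors the statistics conventionally reported for smoking-status
classifiers: overall accuracy with an exact (Clopper–Pearson) 95% CI, the
no-information rate (NIR — the accuracy of always predicting the largest
observed class) with a one-sided exact binomial test of accuracy > NIR,
unweighted Cohen's kappa, and one-vs-rest sensitivity / specificity / PPV /
NPV per class.  The matrix is oriented predicted-rows × actual-columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AlignmentError, FormatError, ValidationError


@dataclass
class ClassStats:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


@dataclass
class ConfusionSummary:
    """Full evaluation of a predicted-vs-actual label comparison."""

    classes: list[str]
    matrix: np.ndarray  # predicted rows × actual columns
    accuracy: float
    accuracy_ci95: tuple[float, float]
    nir: float
    p_acc_gt_nir: float
    kappa: float
    per_class: dict[str, ClassStats]
    n: int

    _REQUIRED = (
        "classes",
        "matrix",
        "accuracy",
        "accuracy_ci95",
        "nir",
        "p_acc_gt_nir",
        "kappa",
        "per_class",
        "n",
    )

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "matrix": [[int(c) for c in row] for row in self.matrix],
            "matrix_orientation": "predicted_rows_x_actual_columns",
            "accuracy": self.accuracy,
            "accuracy_ci95": list(self.accuracy_ci95),
            "nir": self.nir,
            "p_acc_gt_nir": self.p_acc_gt_nir,
            "kappa": self.kappa,
            "per_class": {c: s.to_dict() for c, s in self.per_class.items()},
            "n": self.n,
        }

    @classmethod
    def from_dict(cls, d) -> "ConfusionSummary":
        missing = [k for k in cls._REQUIRED if k not in d]
        if missing:
            raise FormatError(f"confusion summary record lacks field(s): {missing}")
        per_class = {
            c: ClassStats(**{k: float(v) for k, v in s.items()})
            for c, s in d["per_class"].items()
        }
        return cls(
            classes=list(d["classes"]),
            matrix=np.asarray(d["matrix"], dtype=int),
            accuracy=float(d["accuracy"]),
            accuracy_ci95=tuple(d["accuracy_ci95"]),
            nir=float(d["nir"]),
            p_acc_gt_nir=float(d["p_acc_gt_nir"]),
            kappa=float(d["kappa"]),
            per_class=per_class,
            n=int(d["n"]),
        )


def nir(actual) -> float:
    """No-information rate: largest observed class proportion."""
    actual = np.asarray(actual)
    if actual.size == 0:
        raise ValidationError("empty label vector")
    _, counts = np.unique(actual, return_counts=True)
    return counts.max() / actual.size


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def confusion_summary(pred, actual, classes: list[str] | None = None) -> ConfusionSummary:
    """Evaluate predictions against actual labels.

    ``classes`` fixes the axis order (default: sorted union of both label
    vocabularies).  For k > 2 classes the per-class block treats each class
    as positive against the rest.
    """
    pred = np.asarray(pred)
    actual = np.asarray(actual)
    if pred.shape != actual.shape:
        raise AlignmentError(
            f"predicted ({pred.size}) and actual ({actual.size}) label counts differ"
        )
    if pred.size == 0:
        raise ValidationError("empty label vectors")
    observed = set(pred.tolist()) | set(actual.tolist())
    if classes is None:
        classes = sorted(observed)
    elif not observed <= set(classes):
        raise ValidationError(f"labels outside class set: {sorted(observed - set(classes))}")
    k = len(classes)
    idx = {c: i for i, c in enumerate(classes)}
    mat = np.zeros((k, k), dtype=int)
    for p, a in zip(pred, actual):
        mat[idx[p], idx[a]] += 1
    n = int(mat.sum())
    trace = int(np.trace(mat))
    accuracy = trace / n

    ci = stats.binomtest(trace, n).proportion_ci(confidence_level=0.95, method="exact")
    nir_val = mat.sum(axis=0).max() / n
    p_gt = stats.binomtest(trace, n, p=nir_val, alternative="greater").pvalue

    row_marg = mat.sum(axis=1) / n
    col_marg = mat.sum(axis=0) / n
    p_e = float(row_marg @ col_marg)
    if p_e >= 1.0:
        warnings.warn(
            "degenerate confusion matrix (expected agreement = 1); kappa set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        kappa = 0.0
    else:
        kappa = (accuracy - p_e) / (1.0 - p_e)

    per_class: dict[str, ClassStats] = {}
    for c in classes:
        i = idx[c]
        tp = mat[i, i]
        fp = mat[i, :].sum() - tp
        fn = mat[:, i].sum() - tp
        tn = n - tp - fp - fn
        per_class[c] = ClassStats(
            sensitivity=_safe_div(tp, tp + fn),
            specificity=_safe_div(tn, tn + fp),
            ppv=_safe_div(tp, tp + fp),
            npv=_safe_div(tn, tn + fn),
        )

    return ConfusionSummary(
        classes=list(classes),
        matrix=mat,
        accuracy=accuracy,
        accuracy_ci95=(float(ci.low), float(ci.high)),
        nir=float(nir_val),
        p_acc_gt_nir=float(p_gt),
        kappa=float(kappa),
        per_class=per_class,
        n=n,
    )
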