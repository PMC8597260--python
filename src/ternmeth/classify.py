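"""Binary threshold rules and the two-stage ternary smoking classifier.

A *score* becomes a *classifier* by fixing a threshold and an orientation.
Ternary (current/former/never) classification is the composition of two
binary rules applied in sequence: stage 1 separates ever from never
smokers; stage 2 then separates current from former smokers, but only among
the samples stage 1 called ever.

Training conventions:

* stage 1's threshold is fit on ever(=current∪former)-vs-never over all
  development samples; stage 2's threshold is fit on current-vs-former over
  the *self-reported* ever smokers (not stage-1 predictions) — at
  application time, by contrast, stage 2 runs on the stage-1 predicted ever
  smokers.  The asymmetry is deliberate: training uses the best available
  truth, application has only the cascade.
* thresholds are the closest-to-(0,1) ROC cut-points and are frozen into
  the classifier; applying a classifier to new data never refits them.
* a score exactly equal to the threshold is assigned to the control class
  (strict inequality defines a case).  Midpoint thresholds make exact ties
  measure-zero in practice.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, TrainingError, ValidationError
from .io_formats import BetaMatrix, SampleSheet, ScoreModel
from .roc_analysis import HIGHER, LOWER, build_roc, optimal_threshold
from .scoring import compute_score


@dataclass
class BinaryRule:
    """A score model plus an oriented, frozen decision threshold."""

    model: ScoreModel
    threshold: float
    direction: str
    case_label: str
    control_label: str

    def __post_init__(self) -> None:
        if not math.isfinite(self.threshold):
            raise ValidationError("threshold must be finite")
        if self.direction not in (HIGHER, LOWER):
            raise ValidationError(f"unknown direction: {self.direction!r}")
        if self.case_label == self.control_label:
            raise ValidationError("case and control labels must differ")

    def decide(self, scores: np.ndarray) -> np.ndarray:
        """Label an array of scores; ties at the threshold go to control."""
        scores = np.asarray(scores, dtype=float)
        if self.direction == HIGHER:
            is_case = scores > self.threshold
        else:
            is_case = scores < self.threshold
        return np.where(is_case, self.case_label, self.control_label)

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "threshold": self.threshold,
            "direction": self.direction,
            "case_label": self.case_label,
            "control_label": self.control_label,
        }

    @classmethod
    def from_dict(cls, d) -> "BinaryRule":
        try:
            return cls(
                model=ScoreModel.from_dict(d["model"]),
                threshold=float(d["threshold"]),
                direction=d["direction"],
                case_label=d["case_label"],
                control_label=d["control_label"],
            )
        except KeyError as exc:
            raise FormatError(f"malformed binary-rule record: missing {exc}") from exc


def apply_binary(
    rule: BinaryRule, beta: BetaMatrix, missing_policy: str = "error"
) -> pd.Series:
    """Score a beta matrix with the rule's model and threshold it."""
    sv = compute_score(beta, rule.model, missing_policy=missing_policy)
    return pd.Series(rule.decide(sv.scores), index=pd.Index(sv.sample_ids), name="label")


@dataclass
class TernaryClassifier:
    """Two binary rules composed into a current/former/never classifier."""

    stage1: BinaryRule  # ever vs never
    stage2: BinaryRule  # current vs former, applied to predicted ever smokers

    def __post_init__(self) -> None:
        if {self.stage1.case_label, self.stage1.control_label} != {"ever", "never"}:
            raise ValidationError("stage 1 must separate 'ever' from 'never'")
        if {self.stage2.case_label, self.stage2.control_label} != {"current", "former"}:
            raise ValidationError("stage 2 must separate 'current' from 'former'")

    def to_dict(self) -> dict:
        return {"stage1": self.stage1.to_dict(), "stage2": self.stage2.to_dict()}

    @classmethod
    def from_dict(cls, d) -> "TernaryClassifier":
        try:
            return cls(
                stage1=BinaryRule.from_dict(d["stage1"]),
                stage2=BinaryRule.from_dict(d["stage2"]),
            )
        except KeyError as exc:
            raise FormatError(f"malformed classifier record: missing {exc}") from exc

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "TernaryClassifier":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def apply_ternary(
    clf: TernaryClassifier, beta: BetaMatrix, missing_policy: str = "error"
) -> pd.Series:
    """Cascade the two rules: never is final; ever goes on to stage 2."""
    stage1 = apply_binary(clf.stage1, beta, missing_policy=missing_policy)
    labels = pd.Series("never", index=stage1.index, name="label")
    ever_ids = stage1.index[stage1 == "ever"]
    if len(ever_ids) > 0:
        stage2 = apply_binary(
            clf.stage2, beta.subset_samples(list(ever_ids)), missing_policy=missing_policy
        )
        labels.loc[ever_ids] = stage2
    return labels


def _train_rule(
    beta: BetaMatrix,
    case_mask: pd.Series,
    model: ScoreModel,
    case_label: str,
    control_label: str,
    missing_policy: str = "error",
) -> BinaryRule:
    sv = compute_score(beta, model, missing_policy=missing_policy)
    y = case_mask.loc[sv.sample_ids].to_numpy(dtype=bool)
    if y.all() or not y.any():
        absent = control_label if y.all() else case_label
        raise TrainingError(f"cannot fit {case_label}/{control_label} rule: no "
                            f"{absent!r} samples in the training data")
    curve = build_roc(sv.scores, y, direction="auto")
    thr = optimal_threshold(curve)
    return BinaryRule(model, thr, curve.direction, case_label, control_label)


def train_ternary(
    beta: BetaMatrix,
    sheet: SampleSheet,
    model_ever: ScoreModel,
    model_cf: ScoreModel,
    missing_policy: str = "error",
) -> TernaryClassifier:
    """Fit both thresholds on development data and freeze them.

    Stage 1 is fit on all samples (ever vs never); stage 2 on the
    self-reported ever smokers only (current vs former).  All three classes
    must be present.  Retraining on identical input is bit-identical.
    """
    status = sheet.status()
    ids = [s for s in beta.sample_ids if s in status.index]
    if len(ids) != len(beta.sample_ids) or len(ids) != len(status):
        raise TrainingError("beta matrix and sample sheet cover different samples")
    status = status.loc[ids]
    for cls in ("current", "former", "never"):
        if (status == cls).sum() == 0:
            raise TrainingError(f"training data contain no {cls!r} smokers")

    stage1 = _train_rule(
        beta, status.isin(["current", "former"]), model_ever, "ever", "never",
        missing_policy,
    )
    ever_ids = list(status.index[status.isin(["current", "former"])])
    stage2 = _train_rule(
        beta.subset_samples(ever_ids),
        status.loc[ever_ids] == "current",
        model_cf,
        "current",
        "former",
        missing_policy,
    )
    return TernaryClassifier(stage1, stage2)
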