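"""Weighted DNAm classification scores.

A classification score for a sample is the intercept plus the sum over model
CpGs of (weight × beta value).  This is the standard construction for
methylation biomarker scores of smoking; it is linear in the betas, so all
discrimination comes from the weights chosen upstream (literature effect
sizes or LASSO coefficients).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import MissingCpGError, ValidationError
from .io_formats import BetaMatrix, ScoreModel


@dataclass
class ScoreVector:
    """Per-sample scores, aligned with ``sample_ids``."""

    sample_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or len(self.scores) != len(self.sample_ids):
            raise ValidationError("one score per sample required")
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError("scores must be finite")

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=pd.Index(self.sample_ids), name="score")

    @classmethod
    def from_series(cls, s: pd.Series) -> "ScoreVector":
        return cls(list(s.index), s.to_numpy(dtype=float))

    def __len__(self) -> int:
        return len(self.sample_ids)


def compute_score(
    beta: BetaMatrix, model: ScoreModel, missing_policy: str = "error"
) -> ScoreVector:
    """Compute ``intercept + Σ_j weight_j · beta(cpg_j, sample)`` per sample.

    Parameters
    ----------
    beta
        CpG × sample matrix; must contain every model CpG.
    model
        Weighted-CpG score definition.
    missing_policy
        ``"error"`` (default) rejects any missing beta at a model CpG;
        ``"mean_impute"`` replaces a missing value with the mean of the
        non-missing values of that CpG across samples.  Imputation is opt-in
        because it silently changes classifications near thresholds.
    """
    if missing_policy not in ("error", "mean_impute"):
        raise ValueError(f"unknown missing_policy: {missing_policy!r}")
    absent = [c for c in model.cpg_ids if c not in beta.values.index]
    if absent:
        raise MissingCpGError(
            f"model {model.name!r} CpG(s) absent from beta matrix: {absent[:5]}"
        )
    sub = beta.values.loc[model.cpg_ids]
    arr = sub.to_numpy(dtype=float, copy=True)
    nan_mask = np.isnan(arr)
    if nan_mask.any():
        if missing_policy == "error":
            i, j = np.argwhere(nan_mask)[0]
            raise ValidationError(
                f"missing beta at CpG {sub.index[i]!r}, sample {sub.columns[j]!r} "
                "(use missing_policy='mean_impute' to impute)"
            )
        all_missing = nan_mask.all(axis=1)
        if all_missing.any():
            cpg = sub.index[np.argwhere(all_missing)[0][0]]
            raise ValidationError(f"CpG {cpg!r} has no non-missing values to impute from")
        row_means = np.nanmean(arr, axis=1)
        arr = np.where(nan_mask, row_means[:, None], arr)
    weights = np.array([w for _, w in model.terms], dtype=float)
    scores = model.intercept + weights @ arr
    return ScoreVector(beta.sample_ids, scores)
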