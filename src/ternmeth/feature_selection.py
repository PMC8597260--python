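"""Cross-validated L1-penalized logistic feature selection for CpG scores.

Given a beta matrix, binary labels, and an optional candidate CpG list,
``lasso_select`` fits an L1-penalized logistic regression over a log-spaced
grid of penalties (from the smallest penalty that zeroes every coefficient
down three decades), picks the penalty minimizing the mean k-fold
cross-validated binomial deviance, and exports the nonzero coefficients as
a :class:`~ternmeth.io_formats.ScoreModel` — so the selected score is a
plain weighted sum of betas, self-contained and portable.

A parameter cap (typically a Riley bound from :mod:`ternmeth.sample_size`)
can be imposed: if the deviance-optimal model exceeds it, the smallest
penalty whose model respects the cap is used instead and the substitution
is flagged in the diagnostics.

Predictors are *not* standardized by default, because exported weights must
apply to raw beta values; with ``standardize=True`` the fit runs on z-scored
predictors and the weights are transformed back to the beta scale before
export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ._cd_lasso import l1_logistic_path
from .exceptions import DegenerateInputError, MissingCpGError, ValidationError
from .io_formats import BetaMatrix, ScoreModel

#: probability floor when accumulating held-out deviance
_EPS = 1e-12


@dataclass(frozen=True)
class LassoSpec:
    """Selection settings; everything random is derived from ``seed``."""

    seed: int
    k_folds: int = 5
    n_lambda: int = 100
    lambda_rule: str = "min_cv_error"
    candidate_cpgs: tuple[str, ...] | None = None
    parameter_cap: int | None = None
    standardize: bool = False
    lambda_decades: float = 3.0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValidationError("k_folds must be at least 2")
        if self.n_lambda < 2:
            raise ValidationError("n_lambda must be at least 2")
        if self.lambda_rule != "min_cv_error":
            raise ValidationError(f"unknown lambda rule: {self.lambda_rule!r}")
        if self.parameter_cap is not None and self.parameter_cap < 1:
            raise ValidationError("parameter_cap must be positive")


def _deviance(coef: np.ndarray, intercept: float, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ coef + intercept
    p = np.clip(1.0 / (1.0 + np.exp(-eta)), _EPS, 1.0 - _EPS)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1.0 - p)))


def lasso_select(
    beta: BetaMatrix, labels, spec: LassoSpec, name: str = "lasso"
) -> tuple[ScoreModel, dict]:
    """Select a weighted-CpG score by cross-validated L1 logistic regression.

    Parameters
    ----------
    beta
        CpG × sample matrix (no missing values among the candidate CpGs).
    labels
        Boolean case indicator aligned with ``beta``'s samples.
    spec
        Fold count, grid size, seed, optional candidate list and cap.
    name
        Name for the returned score model.

    Returns
    -------
    model, diagnostics
        The score model (nonzero terms plus intercept) and a diagnostics
        dict with the λ grid, per-λ mean CV deviance, per-λ nonzero counts
        on the full-data path, the chosen λ, and whether the parameter cap
        displaced the deviance-optimal λ.
    """
    y = np.asarray(labels, dtype=bool)
    if y.size != len(beta.sample_ids):
        raise ValidationError("labels must align with the beta matrix samples")
    if y.all() or not y.any():
        raise DegenerateInputError("labels contain a single class")

    if spec.candidate_cpgs is not None:
        missing = [c for c in spec.candidate_cpgs if c not in beta.values.index]
        if missing:
            raise MissingCpGError(f"candidate CpG(s) absent from matrix: {missing[:5]}")
        frame = beta.values.loc[list(spec.candidate_cpgs)]
    else:
        frame = beta.values
    cpgs = list(frame.index)
    X = frame.to_numpy(dtype=float).T  # samples × CpGs
    if np.isnan(X).any():
        raise ValidationError("beta matrix has missing values among candidate CpGs")
    yi = y.astype(int)

    if spec.standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        if (sd == 0).any():
            raise ValidationError("constant CpG cannot be standardized")
        X_fit = (X - mu) / sd
    else:
        X_fit = X

    # λ_max: smallest penalty shrinking every coefficient to zero
    n = len(yi)
    resid = yi - yi.mean()
    lam_max = float(np.max(np.abs(X_fit.T @ resid)) / n)
    if lam_max <= 0:
        raise DegenerateInputError("predictors carry no gradient at the null model")
    lambdas = lam_max * np.logspace(0.0, -spec.lambda_decades, spec.n_lambda)

    folds = StratifiedKFold(n_splits=spec.k_folds, shuffle=True, random_state=spec.seed)
    cv_dev = np.zeros(spec.n_lambda)
    for train_idx, test_idx in folds.split(X_fit, yi):
        fold_coefs, fold_icepts = l1_logistic_path(X_fit[train_idx], yi[train_idx], lambdas)
        for j in range(spec.n_lambda):
            cv_dev[j] += _deviance(
                fold_coefs[j], fold_icepts[j], X_fit[test_idx], yi[test_idx]
            )
    cv_dev /= n  # mean held-out deviance per sample

    path_coefs, path_icepts = l1_logistic_path(X_fit, yi, lambdas)
    nonzero = (path_coefs != 0).sum(axis=1)

    best_j = int(np.argmin(cv_dev))  # grid descends, so ties favour the sparser model
    cap_applied = False
    if spec.parameter_cap is not None and nonzero[best_j] > spec.parameter_cap:
        ok = np.flatnonzero(nonzero <= spec.parameter_cap)
        # smallest λ whose model respects the cap (grid is descending)
        best_j = int(ok[-1]) if ok.size else 0
        cap_applied = True

    coef = path_coefs[best_j].copy()
    intercept = float(path_icepts[best_j])
    if spec.standardize:
        intercept -= float(np.sum(coef * mu / sd))
        coef = coef / sd

    terms = [(cpgs[i], float(coef[i])) for i in np.flatnonzero(coef)]
    if not terms:
        # an all-zero selection is a legitimate outcome on null data; export
        # the intercept-only model as a single zero-weight term on the first
        # candidate so the ScoreModel contract (≥1 term) holds
        terms = [(cpgs[0], 0.0)]
    model = ScoreModel(name, terms, intercept)

    diagnostics = {
        "lambdas": lambdas.tolist(),
        "cv_deviance_mean": cv_dev.tolist(),
        "nonzero_counts": nonzero.tolist(),
        "lambda_selected": float(lambdas[best_j]),
        "lambda_min_cv": float(lambdas[int(np.argmin(cv_dev))]),
        "n_selected": int(np.sum(coef != 0)),
        "cap_applied": cap_applied,
        "standardized": spec.standardize,
    }
    return model, diagnostics
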