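"""ROC construction, DeLong AUC inference, and the closest-to-(0,1) threshold.

AUC here is the Mann–Whitney concordance — the probability that a random
case scores above a random control, with half-credit for ties.  Variances,
confidence intervals and the paired comparison of two correlated AUCs use
DeLong's structural-components (fast midrank) method; the paired comparison
is the DeLong Z-test used to compare candidate smoking scores against a
single-CpG AHRR-style reference.

The operating threshold for a score is the ROC cut-point minimizing the
Euclidean distance to the perfect-classification corner (sens = spec = 1).
Candidate cut-points are midpoints between consecutive distinct score
values (the convention of the common R ROC tooling), so exact ties between
a sample score and a threshold are measure-zero in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import AlignmentError, DegenerateInputError
from .scoring import ScoreVector

HIGHER = "higher_is_case"
LOWER = "lower_is_case"


@dataclass
class RocCurve:
    """Operating points of a score against binary labels.

    ``thresholds`` ascend and include −∞/+∞ sentinels so the trivial
    operating points (sens=1, spec=0) and (sens=0, spec=1) are always
    present.  Under ``higher_is_case``, a sample is called a case when its
    score is strictly above the threshold.
    """

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    direction: str

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.sensitivities = np.asarray(self.sensitivities, dtype=float)
        self.specificities = np.asarray(self.specificities, dtype=float)
        if not (
            len(self.thresholds) == len(self.sensitivities) == len(self.specificities)
        ):
            raise ValueError("threshold/sensitivity/specificity lengths differ")
        if self.direction not in (HIGHER, LOWER):
            raise ValueError(f"unknown direction: {self.direction!r}")


@dataclass
class AucResult:
    """AUC with its DeLong variance and normal-approximation 95% CI."""

    auc: float
    variance: float
    ci95: tuple[float, float]


@dataclass
class DelongComparison:
    """Paired DeLong Z-test of two correlated AUCs on the same samples."""

    z: float
    p: float
    auc_a: float
    auc_b: float


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(scores, ScoreVector):
        scores = scores.scores
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise AlignmentError(
            f"scores ({scores.shape}) and labels ({labels.shape}) differ in length"
        )
    if labels.all() or not labels.any():
        raise DegenerateInputError("labels contain a single class")
    return scores, labels


def _mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Concordance P(case > control) + ½·P(tie), via midranks."""
    ranks = stats.rankdata(scores)
    m = int(labels.sum())
    n = len(scores) - m
    return (ranks[labels].sum() - m * (m + 1) / 2.0) / (m * n)


def resolve_direction(scores, labels, direction: str = "auto") -> str:
    """Pick the orientation whose AUC is ≥ 0.5 when asked to auto-detect.

    Needed because some smoking CpGs (e.g. AHRR cg05575921) are *hypo*-
    methylated in smokers, so the case class sits below the threshold.
    """
    if direction in (HIGHER, LOWER):
        return direction
    if direction != "auto":
        raise ValueError(f"unknown direction: {direction!r}")
    s, y = _as_arrays(scores, labels)
    return HIGHER if _mann_whitney_auc(s, y) >= 0.5 else LOWER


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


def build_roc(scores, labels, direction: str = "auto") -> RocCurve:
    """Enumerate all operating points of a score against binary labels.

    ``labels`` is a boolean case indicator aligned positionally with the
    scores.  ``direction="auto"`` orients the score so its AUC is ≥ 0.5.
    """
    s, y = _as_arrays(scores, labels)
    direction = resolve_direction(s, y, direction)
    thr = _candidate_thresholds(s)
    cases, controls = s[y], s[~y]
    if direction == HIGHER:
        sens = (cases[None, :] > thr[:, None]).mean(axis=1)
        spec = (controls[None, :] <= thr[:, None]).mean(axis=1)
    else:
        sens = (cases[None, :] < thr[:, None]).mean(axis=1)
        spec = (controls[None, :] >= thr[:, None]).mean(axis=1)
    return RocCurve(thr, sens, spec, direction)


def optimal_threshold(curve: RocCurve) -> float:
    """Threshold minimizing √((1−sens)² + (1−spec)²); ties → smallest.

    Only finite candidate thresholds qualify; a curve with none (all scores
    identical) is uninformative and rejected.
    """
    finite = np.isfinite(curve.thresholds)
    if not finite.any():
        raise DegenerateInputError(
            "all scores are identical: the score is uninformative, no threshold exists"
        )
    thr = curve.thresholds[finite]
    d = np.hypot(1.0 - curve.sensitivities[finite], 1.0 - curve.specificities[finite])
    best = d.min()
    # smallest threshold among (numerically) tied minima
    return float(thr[d <= best + 1e-12][0])


# ---------------------------------------------------------------------------
# DeLong machinery
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_structural(scores: np.ndarray, labels: np.ndarray):
    """AUCs and structural-component covariances for k score vectors.

    ``scores`` has shape (k, n).  Returns (aucs, S) where S is the k×k
    covariance matrix of the AUC estimates (already divided by the class
    sizes), following DeLong/DeLong/Clarke-Pearson with midranks.
    """
    cases = scores[:, labels]
    controls = scores[:, ~labels]
    m, n0 = cases.shape[1], controls.shape[1]
    k = scores.shape[0]
    v01 = np.empty((k, m))
    v10 = np.empty((k, n0))
    aucs = np.empty(k)
    for r in range(k):
        tx = _midrank(cases[r])
        ty = _midrank(controls[r])
        tz = _midrank(np.concatenate([cases[r], controls[r]]))
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n0)
        v01[r] = (tz[:m] - tx) / n0          # placements of cases among controls
        v10[r] = 1.0 - (tz[m:] - ty) / m     # placements of controls among cases
    ddof = 1
    sx = np.cov(v01, ddof=ddof).reshape(k, k) if m > 1 else np.zeros((k, k))
    sy = np.cov(v10, ddof=ddof).reshape(k, k) if n0 > 1 else np.zeros((k, k))
    S = sx / m + sy / n0
    return aucs, S


def auc(scores, labels, direction: str = HIGHER) -> AucResult:
    """Mann–Whitney AUC with DeLong variance and truncated normal 95% CI."""
    s, y = _as_arrays(scores, labels)
    direction = resolve_direction(s, y, direction)
    if direction == LOWER:
        s = -s
    aucs, S = _delong_structural(s[None, :], y)
    a, var = float(aucs[0]), float(max(S[0, 0], 0.0))
    half = stats.norm.ppf(0.975) * math.sqrt(var)
    ci = (max(0.0, a - half), min(1.0, a + half))
    return AucResult(a, var, ci)


def delong_test(
    scores_a,
    scores_b,
    labels,
    direction_a: str = "auto",
    direction_b: str = "auto",
) -> DelongComparison:
    """Paired DeLong Z-test for the difference of two correlated AUCs.

    Both score vectors must cover the same samples in the same order (they
    are evaluated against one shared label vector).  Each score is oriented
    independently (``auto`` flips a score whose AUC would fall below 0.5),
    mirroring how differently-signed biomarkers are compared in practice.
    """
    if isinstance(scores_a, ScoreVector) and isinstance(scores_b, ScoreVector):
        if scores_a.sample_ids != scores_b.sample_ids:
            raise AlignmentError("score vectors cover different sample sets")
    sa, y = _as_arrays(scores_a, labels)
    sb, y2 = _as_arrays(scores_b, labels)
    if len(sa) != len(sb):
        raise AlignmentError("score vectors differ in length")
    assert np.array_equal(y, y2)
    if resolve_direction(sa, y, direction_a) == LOWER:
        sa = -sa
    if resolve_direction(sb, y, direction_b) == LOWER:
        sb = -sb
    if min(y.sum(), (~y).sum()) < 2:
        raise DegenerateInputError("need at least 2 cases and 2 controls")
    aucs, S = _delong_structural(np.vstack([sa, sb]), y)
    diff = float(aucs[0] - aucs[1])
    var = float(S[0, 0] + S[1, 1] - 2.0 * S[0, 1])
    if var <= 0.0:
        z = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    else:
        z = diff / math.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z))) if math.isfinite(z) else 0.0
    p = max(p, np.nextafter(0.0, 1.0))
    return DelongComparison(z=z, p=p, auc_a=float(aucs[0]), auc_b=float(aucs[1]))
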