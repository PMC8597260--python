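"""Riley minimum-sample-size criteria, inverted to cap model size.

For a binary-outcome prediction model developed on ``n`` samples with
outcome proportion ``phi`` and an anticipated apparent fit ``R²``, Riley's
criteria bound the number of candidate parameters ``p`` so that:

1. the expected global uniform shrinkage factor S is at least a target
   (default 0.9 — at most ~10% overfitting-driven coefficient shrinkage):
   ``p ≤ n·(S − 1)·ln(1 − R²_cs / S)``;
2. the optimism in apparent fit is small — the absolute difference between
   apparent and optimism-adjusted Nagelkerke R² is at most ``delta``
   (default 0.05).  Converted to the Cox–Snell scale (Nagelkerke =
   Cox–Snell / max Cox–Snell), this fixes a required shrinkage
   ``S₂ = R²_cs / (R²_cs + delta · max R²_cs)`` and the same bound formula
   applies with S₂;
3. the null-model outcome proportion is estimated with a margin of error
   ≤ 0.05: ``n ≥ z²·φ(1−φ)/margin²``.  This constrains n, not p, so it is
   reported as a feasibility flag.

``max R²_cs = 1 − exp(2·lnL_null/n)`` with
``lnL_null = n·(φ·ln φ + (1−φ)·ln(1−φ))``.

The anticipated R² may be supplied on the Nagelkerke scale (converted via
max R²_cs before use) or directly on the Cox–Snell scale — the scale the
published formulas, and the reference R implementation of them, operate on.
The parameter bounds are floored (conservative), and the cap on a model is
the minimum of the two bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .exceptions import ValidationError


@dataclass(frozen=True)
class RileySpec:
    """Inputs to the three binary-outcome criteria.

    ``r2_apparent`` is the anticipated apparent R² of the model, interpreted
    per ``r2_scale`` ("nagelkerke" or "cox_snell").
    """

    n: int
    phi: float
    r2_apparent: float
    r2_scale: str = "nagelkerke"
    shrinkage_target: float = 0.9
    optimism_delta: float = 0.05
    margin: float = 0.05
    z: float = 1.96

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("n must be at least 2")
        if not 0.0 < self.phi < 1.0:
            raise ValidationError("outcome proportion phi must lie strictly in (0, 1)")
        if not 0.0 < self.r2_apparent < 1.0:
            raise ValidationError("apparent R² must lie strictly in (0, 1)")
        if not 0.0 < self.shrinkage_target < 1.0:
            raise ValidationError("shrinkage target must lie strictly in (0, 1)")
        if self.r2_scale not in ("nagelkerke", "cox_snell"):
            raise ValidationError(f"unknown r2_scale: {self.r2_scale!r}")
        if self.optimism_delta <= 0 or self.margin <= 0 or self.z <= 0:
            raise ValidationError("optimism_delta, margin and z must be positive")


@dataclass
class RileyResult:
    """Parameter bounds plus every intermediate, for audit."""

    p_crit_shrinkage: int
    p_crit_optimism: int
    margin_ok: bool
    p_max: int
    intermediates: dict = field(default_factory=dict)


def _p_bound(n: int, r2_cs: float, s: float) -> float:
    if r2_cs >= s:
        raise ValidationError(
            f"apparent Cox–Snell R² ({r2_cs:.4f}) must be below the shrinkage "
            f"factor ({s:.4f}) for the bound to exist"
        )
    return n * (s - 1.0) * math.log(1.0 - r2_cs / s)


def max_parameters(spec: RileySpec) -> RileyResult:
    """Maximum parameter count satisfying the shrinkage and optimism criteria.

    Returns floored integer bounds for criteria 1 and 2, a feasibility flag
    for criterion 3 (which constrains n, not p), and their minimum as
    ``p_max``.  All intermediates are recorded for audit.
    """
    n, phi = spec.n, spec.phi
    lnl_null = n * (phi * math.log(phi) + (1.0 - phi) * math.log(1.0 - phi))
    max_r2_cs = 1.0 - math.exp(2.0 * lnl_null / n)
    if spec.r2_scale == "nagelkerke":
        r2_cs = spec.r2_apparent * max_r2_cs
    else:
        r2_cs = spec.r2_apparent
        if r2_cs >= max_r2_cs:
            raise ValidationError(
                f"Cox–Snell R² ({r2_cs:.4f}) exceeds its attainable maximum "
                f"({max_r2_cs:.4f}) at phi={phi:.3f}"
            )

    p1 = _p_bound(n, r2_cs, spec.shrinkage_target)
    s2 = r2_cs / (r2_cs + spec.optimism_delta * max_r2_cs)
    p2 = _p_bound(n, r2_cs, s2)

    n_margin = spec.z**2 * phi * (1.0 - phi) / spec.margin**2
    margin_ok = n >= n_margin

    p_crit_shrinkage = max(0, math.floor(p1))
    p_crit_optimism = max(0, math.floor(p2))
    return RileyResult(
        p_crit_shrinkage=p_crit_shrinkage,
        p_crit_optimism=p_crit_optimism,
        margin_ok=margin_ok,
        p_max=min(p_crit_shrinkage, p_crit_optimism),
        intermediates={
            "ln_likelihood_null": lnl_null,
            "max_r2_cox_snell": max_r2_cs,
            "r2_cox_snell_apparent": r2_cs,
            "shrinkage_criterion2": s2,
            "p_bound_shrinkage_raw": p1,
            "p_bound_optimism_raw": p2,
            "n_required_margin": n_margin,
        },
    )
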