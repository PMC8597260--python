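"""Synthetic methylation cohorts with smoking-like cluster structure.

The generator emulates the statistical structure that makes ternary smoking
classification from blood DNAm possible at all: smoking-associated CpGs fall
into behaviour classes according to whether their methylation returns to
never-smoker levels after cessation.

* **persistent** CpGs are shifted in *all* ever smokers (current and former)
  — decades-stable signals that separate ever from never smokers;
* **reverting** CpGs are shifted in current smokers only — fast-reverting
  signals that separate current from former smokers;
* **partial** CpGs place former smokers a configurable fraction of the way
  between never (0) and current (1) levels, creating the intermediate,
  overlapping former-smoker cluster seen in real cohorts;
* **null** CpGs carry no signal.

Per CpG, a never-smoker baseline mean is drawn uniformly from
``baseline_range`` and each behaviour's shift is applied on the beta scale
with a random sign (real smoking CpGs are a mix of hyper- and
hypo-methylated).  Individual beta values are drawn around the class mean on
the logit scale with ``noise_sd`` and mapped back through the logistic, so
every value lies strictly in (0, 1).

What this deliberately does not model: probe-type chemistry, batch and
study effects, cell-composition mixtures, age/sex confounding, and
per-individual time-since-cessation dynamics (former-smoker heterogeneity is
a single interpolation parameter, not a quit-time distribution).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .exceptions import ValidationError
from .io_formats import BetaMatrix, SampleSheet, ScoreModel

BEHAVIOURS = ("persistent", "reverting", "partial", "null")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design knobs for one simulated cohort.

    Defaults give a balanced 600-sample cohort and 500 CpGs of which 150
    carry signal, with beta-scale shifts of 0.15 and logit-scale noise 0.5 —
    calibrated so that oracle scores reach the AUC ranges reported for
    smoking scores on real 450K data (ever/never well above 0.9).
    """

    n_current: int = 200
    n_former: int = 200
    n_never: int = 200
    n_persistent: int = 50
    n_reverting: int = 50
    n_partial: int = 50
    n_null: int = 350
    effect_persistent: float = 0.15
    effect_reverting: float = 0.15
    effect_partial: float = 0.15
    former_fraction_partial: float = 0.5
    noise_sd: float = 0.5
    baseline_range: tuple[float, float] = (0.2, 0.8)
    seed: int = 0
    #: seed for the CpG-level architecture (baselines, effect signs).  Two
    #: cohorts sharing this but differing in ``seed`` represent new
    #: individuals measured on the same biology — the development /
    #: external-validation situation.  None: derived from ``seed``.
    architecture_seed: int | None = None

    def __post_init__(self) -> None:
        counts = (self.n_current, self.n_former, self.n_never)
        cpgs = (self.n_persistent, self.n_reverting, self.n_partial, self.n_null)
        if min(counts) < 0 or min(cpgs) < 0:
            raise ValidationError("counts must be non-negative")
        if sum(cpgs) < 1:
            raise ValidationError("at least one CpG required")
        if sum(counts) < 2:
            raise ValidationError("at least two samples required")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        lo, hi = self.baseline_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValidationError("baseline_range must lie within (0, 1)")
        if not 0.0 <= self.former_fraction_partial <= 1.0:
            raise ValidationError("former_fraction_partial must lie in [0, 1]")
        worst = max(
            abs(self.effect_persistent), abs(self.effect_reverting), abs(self.effect_partial)
        )
        if lo - worst <= 0.0 or hi + worst >= 1.0:
            raise ValidationError(
                "shifted class means would leave (0, 1): shrink the effects or the "
                "baseline range"
            )

    @property
    def n_samples(self) -> int:
        return self.n_current + self.n_former + self.n_never

    @property
    def n_cpgs(self) -> int:
        return self.n_persistent + self.n_reverting + self.n_partial + self.n_null


def generate(config: SyntheticConfig) -> tuple[BetaMatrix, SampleSheet, pd.DataFrame]:
    """Simulate one cohort; deterministic given the config seeds.

    Returns the beta matrix, the sample sheet, and a truth table (one row
    per CpG: behaviour, signed effect, and the true class means) so that
    recovery tests never have to re-derive ground truth.  Cohorts sharing
    ``architecture_seed`` have identical truth tables (same CpG biology)
    while ``seed`` drives the per-individual measurements.
    """
    arch_seed = (
        config.architecture_seed if config.architecture_seed is not None else config.seed
    )
    rng_arch = np.random.default_rng(arch_seed)
    rng = np.random.default_rng(config.seed)
    n_cpg, n_smp = config.n_cpgs, config.n_samples

    behaviours = np.repeat(
        BEHAVIOURS,
        [config.n_persistent, config.n_reverting, config.n_partial, config.n_null],
    )
    cpg_ids = [f"cg{i + 1:08d}" for i in range(n_cpg)]
    baselines = rng_arch.uniform(*config.baseline_range, size=n_cpg)
    signs = rng_arch.choice([-1.0, 1.0], size=n_cpg)
    magnitude = np.select(
        [behaviours == "persistent", behaviours == "reverting", behaviours == "partial"],
        [config.effect_persistent, config.effect_reverting, config.effect_partial],
        default=0.0,
    )
    effects = signs * magnitude

    mean_never = baselines
    mean_current = baselines + effects
    mean_former = np.where(
        behaviours == "persistent",
        baselines + effects,
        np.where(
            behaviours == "partial",
            baselines + config.former_fraction_partial * effects,
            baselines,  # reverting and null: back at never level
        ),
    )

    status = np.repeat(
        ["current", "former", "never"],
        [config.n_current, config.n_former, config.n_never],
    )
    sample_ids = [f"S{i + 1:05d}" for i in range(n_smp)]
    class_means = {
        "current": mean_current,
        "former": mean_former,
        "never": mean_never,
    }
    values = np.empty((n_cpg, n_smp))
    for cls in ("current", "former", "never"):
        cols = status == cls
        if not cols.any():
            continue
        mu = logit(class_means[cls])[:, None]
        values[:, cols] = expit(
            mu + rng.normal(0.0, config.noise_sd, size=(n_cpg, int(cols.sum())))
        )

    beta = BetaMatrix(pd.DataFrame(values, index=cpg_ids, columns=sample_ids))
    sheet = SampleSheet(
        pd.DataFrame({"status": status}, index=pd.Index(sample_ids, name="sample_id"))
    )
    truth = pd.DataFrame(
        {
            "behaviour": behaviours,
            "baseline": baselines,
            "effect": effects,
            "mean_never": mean_never,
            "mean_former": mean_former,
            "mean_current": mean_current,
        },
        index=pd.Index(cpg_ids, name="cpg_id"),
    )
    return beta, sheet, truth


def oracle_models(truth: pd.DataFrame) -> tuple[ScoreModel, ScoreModel]:
    """Truth-derived score models: the generator's own separating axes.

    Stage 1 (ever vs never) weights the persistent CpGs by the sign of their
    true effect; stage 2 (current vs former) does the same with the
    reverting CpGs.  Useful as known-good scores in end-to-end tests.
    """
    def _model(name: str, behaviour: str) -> ScoreModel:
        rows = truth[truth["behaviour"] == behaviour]
        if rows.empty:
            raise ValidationError(f"truth table has no {behaviour!r} CpGs")
        # sign carries all the information; unit weight when there is no effect
        # (null designs) so the score stays non-constant
        terms = [(cpg, float(np.sign(e)) or 1.0) for cpg, e in rows["effect"].items()]
        return ScoreModel(name, terms)

    return _model("oracle-persistent", "persistent"), _model("oracle-reverting", "reverting")


def single_cpg_reference(truth: pd.DataFrame) -> ScoreModel:
    """A one-CpG reference model, analogous to the AHRR cg05575921 score.

    Picks the first reverting CpG: like the real AHRR site, a fast-reverting
    CpG carries signal for both ever/never (partial) and current/former
    stages, making it the natural single-site baseline to compare richer
    models against.
    """
    rows = truth[truth["behaviour"] == "reverting"]
    if rows.empty:
        raise ValidationError("truth table has no reverting CpGs")
    cpg = rows.index[0]
    return ScoreModel("reference-single-cpg", [(str(cpg), 1.0)])


def presets() -> dict[str, SyntheticConfig]:
    """Named study designs.

    ``paperlike-dev`` and ``paperlike-val`` echo the class compositions of a
    1063-sample development set (364 current / 334 former / 365 never) and a
    717-sample external validation set (260 / 263 / 194); ``weak-former``
    pushes former smokers close to current-smoker levels at partial CpGs,
    emulating a recently-quit cohort.
    """
    base = SyntheticConfig()
    return {
        "default": base,
        "paperlike-dev": replace(base, n_current=364, n_former=334, n_never=365),
        "paperlike-val": replace(base, n_current=260, n_former=263, n_never=194),
        "weak-former": replace(base, former_fraction_partial=0.95),
        "null": replace(
            base,
            effect_persistent=0.0,
            effect_reverting=0.0,
            effect_partial=0.0,
        ),
    }
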