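# Methods

This note documents the statistical procedures `ternmeth` implements, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Scores, thresholds, and the two-stage classifier

A DNAm classification score is a linear functional of the beta values:
`score(i) = β₀ + Σⱼ bⱼ · beta(cpgⱼ, i)`.  Weights apply to beta values on
the 0–1 scale (not M-values, and not the 0–100 percent scale); imported
coefficient tables must match this convention.  Missing betas are rejected
by default; mean imputation across samples at the same CpG is available but
opt-in, because silently imputing near a decision threshold changes class
assignments.

A score becomes a binary rule by fixing a threshold and an orientation.
Candidate thresholds are midpoints between consecutive distinct score
values, with ±∞ sentinels completing the ROC curve at (sens=1, spec=0) and
(sens=0, spec=1).  The operating threshold minimizes
`√((1−sens)² + (1−spec)²)` — the closest point to perfect classification —
with ties broken toward the smallest threshold for determinism.  The
orientation is resolved per score (whichever direction gives AUC ≥ 0.5,
necessary because markers like *AHRR* cg05575921 are hypomethylated in
smokers) and is stored in the rule, never re-learned.  A score exactly
equal to the threshold is assigned to the control class; with midpoint
thresholds such ties have measure zero on continuous data, but the
convention is fixed and tested.

Ternary classification composes two binary rules.  Stage 1 (ever vs never)
is trained on all development samples; stage 2 (current vs former) is
trained on the *self-reported* ever smokers — training uses the best
available truth.  At application time stage 2 sees only the samples stage 1
predicted ever — the cascade has no access to truth.  This asymmetry is
deliberate.  Thresholds are frozen after training; applying a classifier to
new data never refits them, and the pipeline records the classifier file
hash at train and at apply time so the contract is auditable.

## AUC and DeLong inference

AUC is the Mann–Whitney concordance (ties count ½), computed via midranks.
Variances and the paired two-score comparison use DeLong's
structural-components method; the 95% CI is the normal approximation on the
AUC scale truncated to [0, 1].  Whether published CIs of this kind are
DeLong or bootstrap is often unstated; this package uses DeLong throughout
and verifies against a paired stratified bootstrap in its test suite.  The
paired Z-test requires both scores on identical samples; each score is
oriented independently before comparison.

## Evaluation battery

Confusion matrices are predicted-rows × actual-columns.  Accuracy carries
an exact Clopper–Pearson 95% CI; the no-information rate (NIR) is the
largest observed class proportion, and accuracy > NIR is tested with an
exact one-sided binomial test (successes = correct predictions, null
probability = NIR) — the same statistic family as the standard R tooling
(caret).  Unweighted kappa is `(p_o − p_e)/(1 − p_e)` with expected
agreement from marginal products; the degenerate case `p_e = 1` (a single
class on both axes) returns kappa 0 with a warning.  For three classes,
per-class sensitivity/specificity/PPV/NPV are one-vs-rest with the class as
positive; undefined ratios (0/0) are reported as NaN rather than
invented.

## Riley sample-size caps

For a binary-outcome score developed on `n` samples with outcome proportion
φ and anticipated apparent R², the package inverts Riley's minimum-n
criteria into a maximum parameter count: (1) expected global shrinkage
S ≥ 0.9 gives `p ≤ n(S−1)ln(1−R²_cs/S)`; (2) optimism in Nagelkerke R²
≤ 0.05, converted to the Cox–Snell scale via the attainable maximum
`max R²_cs = 1 − exp(2·lnL_null/n)`, fixes the required shrinkage
`S₂ = R²_cs/(R²_cs + δ·max R²_cs)` and the same bound formula applies;
(3) the margin-of-error criterion `n ≥ z²φ(1−φ)/margin²` constrains n, not
p, and is reported as a feasibility flag.  Bounds are floored
(conservative) and the cap is their minimum.  All intermediates are
returned for audit.

The anticipated R² can be supplied on either scale.  Supplied as Nagelkerke
0.609 (its published description), n = 1063/φ = 0.66 and n = 698/φ = 0.52
give caps of 52 and 36; supplied as Cox–Snell 0.609 — the scale the
published formulas and their reference R implementation operate on — the
optimism criterion binds and the caps are 61 and 42.  Both readings are
computed and tested; nothing is forced.  Note the R²→0 limit: the shrinkage
bound (and hence the cap) vanishes, but the optimism bound alone does not,
because its required shrinkage S₂ → 0.

## LASSO score derivation

`lasso_select` fits an L1-penalized logistic regression over a descending
grid of 100 penalties, log-spaced over three decades from λ_max (the
smallest penalty that zeroes every coefficient).  Fold assignment is
stratified by class and fully determined by the seed; the selection loss is
mean held-out binomial deviance, and the deviance-minimizing λ is chosen
(ties favour the stronger penalty).  If a Riley cap is supplied and the
chosen model exceeds it, the smallest λ whose model respects the cap is
used instead and the substitution is flagged in the diagnostics.

Predictors are *not* standardized by default: exported weights must apply
to raw beta values so that a score model file is self-contained.  With
`standardize=True` the fit runs on z-scored predictors and weights are
transformed back to the beta scale before export; the diagnostics record
which path was used.

The path solver is the package's own glmnet-style coordinate descent
(`_cd_lasso`): iteratively reweighted least squares with cyclic
soft-thresholding updates, warm starts along the grid, an active-set sweep
strategy, and internally centered predictors (centering leaves the L1
slopes unchanged and dramatically improves conditioning on all-positive
methylation fractions).  It is deterministic — fixed sweep order, no
randomness — and agrees with R's glmnet to ~1e-9 on fixed grids, which the
test suite checks directly.  One property worth stating precisely: the
nonzero count along the path is *almost* monotone in the penalty, but
single-feature exchanges can produce isolated dips of one; this is inherent
to L1 paths, not a solver artifact, and the tests assert the monotone trend
while tolerating such exchanges.  On pure-noise data the
minimum-CV-deviance rule admits a few spurious features (typically ~2–3% of
a 100-CpG panel on average) — the known behaviour of the minimum rule as
opposed to the one-standard-error rule, which is out of scope because the
selection rule here is minimum mean CV error.

## Synthetic cohorts

The generator realizes the cluster structure that makes ternary smoking
classification possible, with four CpG behaviour classes:

| behaviour  | current      | former                  | never |
|------------|--------------|-------------------------|-------|
| persistent | base + e     | base + e                | base  |
| reverting  | base + e     | base                    | base  |
| partial    | base + e     | base + f·e (f ∈ [0,1])  | base  |
| null       | base         | base                    | base  |

Per CpG, the never-smoker baseline is uniform on `baseline_range`
(default 0.2–0.8) and the shift direction is random (smoking CpGs are a mix
of hyper- and hypomethylated).  Individual betas are drawn on the logit
scale around the class mean with `noise_sd` (default 0.5) and mapped back
through the logistic — a logit-normal model, chosen because it guarantees
(0, 1) support with a single dispersion knob; beta-distributed noise would
add a second shape parameter without changing what the tests probe.  One
consequence: the beta-scale empirical mean is slightly biased toward 0.5
relative to the configured mean (≤ ~0.012 at these settings), which the
convergence tests account for.

Defaults: 200/200/200 current/former/never samples; 50 persistent + 50
reverting + 50 partial + 350 null CpGs; all effects 0.15;
`former_fraction_partial` 0.5 (former smokers midway between never and
current at partial sites).  At these settings the 50-CpG oracle scores
saturate (AUC ≈ 1.0 on their own separating axes) while the single-CpG
reference model sits in the 0.65–0.85 range — the spread between a rich
panel and a single site that motivates multi-CpG scores in the first place.
The `paperlike-dev` (364/334/365, N = 1063) and `paperlike-val`
(260/263/194, N = 717) presets echo a development/external-validation
design with near-balanced classes; `weak-former` pushes
`former_fraction_partial` to 0.95 to emulate a recently-quit cohort whose
former smokers look nearly current.

Cohorts have two seeds: `architecture_seed` fixes the CpG-level biology
(baselines, effect signs) and `seed` the individuals, so a
development/validation pair shares biology while resampling people — the
situation a frozen classifier actually faces.  The truth table (behaviour,
signed effect, true class means per CpG) is always returned so recovery
tests never re-derive ground truth.

Deliberately not modelled: probe-type chemistry and array artifacts, batch
and study effects, cell-composition mixtures, age/sex confounding, and
per-individual time-since-cessation (former-smoker heterogeneity is one
interpolation parameter, not a quit-time distribution).  Passing tests
therefore demonstrate the correctness and calibration of the *methods* on
data with the assumed structure — not the real-data performance of any
particular published score, which depends on normalization, cohort
composition and confounding that this generator does not attempt to
reproduce.

## Numerical conventions

Delimited outputs carry 6 significant digits; JSON reports serialize floats
at full precision so a read-back is bit-exact.  Beta values outside [0, 1]
by more than 1e-9 are rejected with coordinates; within that tolerance they
are clamped.  Probabilities inside the CV deviance are clipped at 1e-12;
the IRLS weights clip fitted probabilities at 1e-5, as is conventional for
GLM path solvers.  All parameter bounds are floored, all CIs truncated to
their natural range, and every stochastic routine takes an explicit seed.

## Problem sizes in the shipped tests

The test suite and acceptance script run at deliberately modest sizes: the
shared unit cohort is 600 × 500, the parameter-recovery fixture 600 × 200
(5 informative CpGs, standardized effect ≈ 1.6), null-calibration cohorts
1000 samples, DeLong calibration 1000–2000 replicates at n = 100, and the
end-to-end run uses the paperlike presets (1063 + 717 samples × 500 CpGs).
These sizes give stable pass/fail behaviour at comfortable margins; scaling
any of them up is a matter of editing a config, not code.
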