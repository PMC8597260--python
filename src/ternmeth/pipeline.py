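"""End-to-end workflow: simulate → cap → select → train → freeze → evaluate.

One :func:`run_pipeline` call reproduces the full shape of a ternary
smoking-classifier study on synthetic data: a development cohort is
simulated and used to (optionally) compute Riley parameter caps, select two
LASSO score models (ever/never on all samples, current/former on the
self-reported ever smokers), and fit the two-stage classifier; a separately
simulated validation cohort is then classified with the *frozen* thresholds
and the whole evaluation battery is computed — AUCs with DeLong comparisons
against a single-CpG reference score, binary confusion summaries for both
stages, and the ternary confusion summary.

Every artifact is stamped with the config hash and seed; the classifier
file hash is recorded both when written (training) and when re-read
(application) so the frozen-threshold contract is auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from .classify import apply_binary, apply_ternary, train_ternary
from .exceptions import ValidationError
from .feature_selection import LassoSpec, lasso_select
from .io_formats import (
    BetaMatrix,
    SampleSheet,
    write_beta_matrix,
    write_report,
    write_sample_sheet,
    write_score_model,
)
from .metrics import confusion_summary
from .roc_analysis import auc, delong_test
from .sample_size import RileySpec, max_parameters
from .scoring import compute_score
from .synthetic_data import generate, oracle_models, presets, single_cpg_reference

logger = logging.getLogger("ternmeth.pipeline")


@dataclass(frozen=True)
class RunConfig:
    """Settings for one pipeline run; JSON-serializable."""

    out_dir: str
    seed: int = 0
    preset_dev: str = "paperlike-dev"
    preset_val: str = "paperlike-val"
    run_maxparams: bool = True
    run_select: bool = True          # False: use the generator's oracle scores
    riley_r2_apparent: float = 0.609
    riley_r2_scale: str = "cox_snell"
    lasso_k_folds: int = 5
    lasso_n_lambda: int = 100
    write_matrices: bool = False
    missing_policy: str = "error"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ValidationError(f"unknown config field(s): {sorted(extra)}")
        if "out_dir" not in d:
            raise ValidationError("config requires 'out_dir'")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _binary_eval(scores_model, scores_ref, y, tag: str) -> dict:
    """AUC of a model score plus its paired DeLong comparison to the reference."""
    a = auc(scores_model.scores, y, direction="auto")
    cmp_ = delong_test(scores_model.scores, scores_ref.scores, y)
    return {
        "task": tag,
        "auc": a.auc,
        "auc_variance": a.variance,
        "auc_ci95": list(a.ci95),
        "delong_vs_reference": {
            "z": cmp_.z,
            "p": cmp_.p,
            "auc_model": cmp_.auc_a,
            "auc_reference": cmp_.auc_b,
        },
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns artefact paths and key results."""
    t_all = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    available = presets()
    for name in (config.preset_dev, config.preset_val):
        if name not in available:
            raise ValidationError(f"unknown preset: {name!r}")

    provenance: dict = {
        "config": config.to_dict(),
        "config_hash": cfg_hash,
        "seed": config.seed,
        "stage_seconds": {},
    }

    def _stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                dt = time.perf_counter() - self.t0
                provenance["stage_seconds"][name] = round(dt, 3)
                if exc[0] is None:
                    logger.info("stage %s finished in %.2fs", name, dt)
                else:
                    logger.error("stage %s failed after %.2fs: %s", name, dt, exc[1])
                return False

        return _Timer()

    # --- simulate ---------------------------------------------------------
    with _stage("simulate"):
        # dev and val share the CpG architecture (same biology, new people)
        cfg_dev = dataclasses.replace(
            available[config.preset_dev], seed=config.seed,
            architecture_seed=config.seed,
        )
        cfg_val = dataclasses.replace(
            available[config.preset_val], seed=config.seed + 1,
            architecture_seed=config.seed,
        )
        beta_dev, sheet_dev, truth_dev = generate(cfg_dev)
        beta_val, sheet_val, truth_val = generate(cfg_val)
        write_sample_sheet(sheet_dev, out / "dev_samples.tsv")
        write_sample_sheet(sheet_val, out / "val_samples.tsv")
        truth_dev.to_csv(out / "dev_truth.tsv", sep="\t")
        truth_val.to_csv(out / "val_truth.tsv", sep="\t")
        if config.write_matrices:
            write_beta_matrix(beta_dev, out / "dev_beta.tsv")
            write_beta_matrix(beta_val, out / "val_beta.tsv")

    status_dev = sheet_dev.status()
    status_val = sheet_val.status()
    y_ever_dev = status_dev.isin(["current", "former"]).to_numpy()
    ever_ids_dev = list(status_dev.index[status_dev.isin(["current", "former"])])
    y_cf_dev = (status_dev.loc[ever_ids_dev] == "current").to_numpy()

    # --- maxparams --------------------------------------------------------
    caps: dict = {"ever_never": None, "current_former": None}
    if config.run_maxparams:
        with _stage("maxparams"):
            riley = {}
            for task, n, phi in (
                ("ever_never", len(status_dev), float(y_ever_dev.mean())),
                ("current_former", len(ever_ids_dev), float(y_cf_dev.mean())),
            ):
                res = max_parameters(
                    RileySpec(
                        n=n,
                        phi=phi,
                        r2_apparent=config.riley_r2_apparent,
                        r2_scale=config.riley_r2_scale,
                    )
                )
                caps[task] = res.p_max
                riley[task] = {
                    "n": n,
                    "phi": phi,
                    "p_crit_shrinkage": res.p_crit_shrinkage,
                    "p_crit_optimism": res.p_crit_optimism,
                    "margin_ok": res.margin_ok,
                    "p_max": res.p_max,
                    "intermediates": res.intermediates,
                }
            write_report({"config_hash": cfg_hash, "riley": riley}, out / "maxparams.json")

    # --- select -----------------------------------------------------------
    with _stage("select"):
        if config.run_select:
            spec_en = LassoSpec(
                seed=config.seed,
                k_folds=config.lasso_k_folds,
                n_lambda=config.lasso_n_lambda,
                parameter_cap=caps["ever_never"],
            )
            model_ever, diag_en = lasso_select(
                beta_dev, y_ever_dev, spec_en, name="lasso-ever-never"
            )
            spec_cf = dataclasses.replace(spec_en, parameter_cap=caps["current_former"])
            model_cf, diag_cf = lasso_select(
                beta_dev.subset_samples(ever_ids_dev),
                y_cf_dev,
                spec_cf,
                name="lasso-current-former",
            )
            write_report(
                {"config_hash": cfg_hash, "ever_never": diag_en, "current_former": diag_cf},
                out / "selection_diagnostics.json",
                human=False,
            )
        else:
            model_ever, model_cf = oracle_models(truth_dev)
        write_score_model(model_ever, out / "model_ever_never.tsv")
        write_score_model(model_cf, out / "model_current_former.tsv")
        reference = single_cpg_reference(truth_dev)

    # --- train ------------------------------------------------------------
    with _stage("train"):
        clf = train_ternary(
            beta_dev, sheet_dev, model_ever, model_cf, missing_policy=config.missing_policy
        )
        clf_path = out / "classifier.json"
        clf.save(clf_path)
        clf_hash_train = _file_hash(clf_path)

    # --- classify (frozen thresholds) ------------------------------------
    with _stage("classify"):
        clf_hash_apply = _file_hash(clf_path)
        from .classify import TernaryClassifier

        clf_applied = TernaryClassifier.load(clf_path)
        pred_val = apply_ternary(clf_applied, beta_val, missing_policy=config.missing_policy)
        pred_val.to_frame().to_csv(out / "val_predictions.tsv", sep="\t", index_label="sample_id")

    # --- evaluate ---------------------------------------------------------
    with _stage("evaluate"):
        y_ever_val = status_val.isin(["current", "former"]).to_numpy()
        ever_ids_val = list(status_val.index[status_val.isin(["current", "former"])])
        y_cf_val = (status_val.loc[ever_ids_val] == "current").to_numpy()
        beta_val_ever = beta_val.subset_samples(ever_ids_val)

        mp = config.missing_policy
        s_en_val = compute_score(beta_val, model_ever, mp)
        s_cf_val = compute_score(beta_val_ever, model_cf, mp)
        r_en_val = compute_score(beta_val, reference, mp)
        r_cf_val = compute_score(beta_val_ever, reference, mp)

        discrimination = {
            "ever_never": _binary_eval(s_en_val, r_en_val, y_ever_val, "ever_never"),
            "current_former": _binary_eval(s_cf_val, r_cf_val, y_cf_val, "current_former"),
        }

        pred_stage1 = apply_binary(clf_applied.stage1, beta_val, mp)
        actual_en = status_val.map(
            lambda s: "ever" if s in ("current", "former") else "never"
        )
        summary_en = confusion_summary(
            pred_stage1.to_numpy(), actual_en.to_numpy(), classes=["ever", "never"]
        )
        pred_stage2 = apply_binary(clf_applied.stage2, beta_val_ever, mp)
        summary_cf = confusion_summary(
            pred_stage2.to_numpy(),
            status_val.loc[ever_ids_val].to_numpy(),
            classes=["current", "former"],
        )
        summary_ternary = confusion_summary(
            pred_val.to_numpy(),
            status_val.to_numpy(),
            classes=["current", "former", "never"],
        )

        report = {
            "config_hash": cfg_hash,
            "seed": config.seed,
            "reference_model": reference.name,
            "discrimination_validation": discrimination,
            "binary_ever_never_validation": summary_en.to_dict(),
            "binary_current_former_validation": summary_cf.to_dict(),
            "ternary_validation": summary_ternary.to_dict(),
        }
        write_report(report, out / "evaluation.json")

    provenance["classifier_hash_train"] = clf_hash_train
    provenance["classifier_hash_apply"] = clf_hash_apply
    provenance["total_seconds"] = round(time.perf_counter() - t_all, 3)
    write_report(provenance, out / "provenance.json", human=False)

    return {
        "out_dir": str(out),
        "config_hash": cfg_hash,
        "classifier": clf,
        "classifier_hash_train": clf_hash_train,
        "classifier_hash_apply": clf_hash_apply,
        "model_ever": model_ever,
        "model_cf": model_cf,
        "reference": reference,
        "caps": caps,
        "evaluation": report,
        "provenance": provenance,
    }
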