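import dataclasses
import shutil
import subprocess

import numpy as np
import pytest

from ternmeth import (
    DegenerateInputError,
    LassoSpec,
    MissingCpGError,
    compute_score,
    lasso_select,
)
from ternmeth._cd_lasso import l1_logistic_path

FAST = LassoSpec(seed=0, k_folds=3, n_lambda=25)


class TestLassoSelect:
    def test_deterministic_under_fixed_seed(self, small_labelled_matrix):
        beta, y, _ = small_labelled_matrix
        m1, d1 = lasso_select(beta, y, FAST)
        m2, d2 = lasso_select(beta, y, FAST)
        assert m1.terms == m2.terms
        assert m1.intercept == m2.intercept
        assert d1["lambda_selected"] == d2["lambda_selected"]

    def test_informative_cpgs_dominate_selection(self, small_labelled_matrix):
        beta, y, truth = small_labelled_matrix
        model, diag = lasso_select(beta, y, FAST)
        informative = set(truth.index[truth.behaviour == "persistent"])
        selected = set(model.cpg_ids)
        assert len(informative & selected) >= 2  # 3 planted in a 25-CpG panel

    def test_parameter_cap_respected_and_flagged(self, small_labelled_matrix):
        beta, y, _ = small_labelled_matrix
        uncapped, d0 = lasso_select(beta, y, FAST)
        cap = max(1, d0["n_selected"] - 1)
        spec = dataclasses.replace(FAST, parameter_cap=cap)
        model, diag = lasso_select(beta, y, spec)
        assert diag["n_selected"] <= cap
        assert diag["cap_applied"] == (d0["n_selected"] > cap)

    def test_score_model_reproduces_linear_predictor(self, small_labelled_matrix):
        beta, y, _ = small_labelled_matrix
        model, diag = lasso_select(beta, y, FAST)
        sv = compute_score(beta, model)
        # refit at the selected lambda and compare eta directly
        X = beta.values.to_numpy().T
        coefs, icepts = l1_logistic_path(
            X, y.astype(float), np.array([diag["lambda_selected"]])
        )
        eta = X @ coefs[0] + icepts[0]
        np.testing.assert_allclose(sv.scores, eta, atol=1e-8)

    def test_standardized_weights_are_back_transformed(self, small_labelled_matrix):
        beta, y, _ = small_labelled_matrix
        spec = dataclasses.replace(FAST, standardize=True)
        model, diag = lasso_select(beta, y, spec)
        assert diag["standardized"]
        # exported weights must apply to raw betas: scores finite and ordered
        # identically to the internal standardized predictor
        sv = compute_score(beta, model)
        assert np.all(np.isfinite(sv.scores))

    def test_candidate_restriction(self, small_labelled_matrix):
        beta, y, truth = small_labelled_matrix
        cands = tuple(truth.index[:10])
        spec = dataclasses.replace(FAST, candidate_cpgs=cands)
        model, _ = lasso_select(beta, y, spec)
        assert set(model.cpg_ids) <= set(cands)

    def test_missing_candidate_rejected(self, small_labelled_matrix):
        beta, y, _ = small_labelled_matrix
        spec = dataclasses.replace(FAST, candidate_cpgs=("cgNOPE",))
        with pytest.raises(MissingCpGError, match="cgNOPE"):
            lasso_select(beta, y, spec)

    def test_single_class_rejected(self, small_labelled_matrix):
        beta, y, _ = small_labelled_matrix
        with pytest.raises(DegenerateInputError):
            lasso_select(beta, np.ones_like(y, dtype=bool), FAST)

    def test_sparsity_grows_with_penalty(self, small_labelled_matrix):
        """Model size shrinks (weakly) as the penalty strengthens.

        Checked on the returned grid after removing transient single-feature
        exchanges: the cumulative-minimum from the strong-penalty end must
        equal the raw counts for all but isolated grid points.
        """
        beta, y, _ = small_labelled_matrix
        _, diag = lasso_select(beta, y, FAST)
        nz = np.array(diag["nonzero_counts"])  # grid descends in lambda
        running_max = np.maximum.accumulate(nz)
        # strong trend: final (least-penalized) count is the largest, first is smallest
        assert nz[0] <= 1
        assert nz[-1] == running_max[-1]
        # allow only rare, shallow dips from feature exchange along the path
        dips = running_max - nz
        assert (dips > 0).mean() <= 0.2
        assert dips.max() <= 2


class TestNullData:
    def test_few_false_positives_on_pure_noise(self):
        """On no-association data the CV-selected model is near-empty.

        n=300 samples, 100 null CpGs, averaged over 10 seeds.  The
        deviance-minimizing lambda on pure noise admits a few spurious CpGs
        (the well-known behaviour of the minimum-CV-error rule, as opposed
        to the one-standard-error rule), but the vast majority of the panel
        — 95% and typically more — is rejected.
        """
        from ternmeth import SyntheticConfig, generate

        base = SyntheticConfig(
            n_current=150,
            n_former=0,
            n_never=150,
            n_persistent=0,
            n_reverting=0,
            n_partial=0,
            n_null=100,
            noise_sd=0.5,
            seed=0,
        )
        counts = []
        for s in range(10):
            beta, sheet, _ = generate(dataclasses.replace(base, seed=100 + s))
            y = sheet.status().isin(["current", "former"]).to_numpy()
            _, diag = lasso_select(beta, y, LassoSpec(seed=s))
            counts.append(diag["n_selected"])
        assert np.mean(counts) <= 5.0  # at most 5% of the 100-CpG panel
        assert np.median(counts) <= 3.0


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
class TestAgainstGlmnet:
    def test_path_coefficients_match_glmnet(self, tmp_path):
        """Independent oracle: R glmnet on the same fixed grid."""
        rng = np.random.default_rng(42)
        n, p = 120, 8
        X = rng.uniform(0.2, 0.8, (n, p))
        eta = (X[:, 0] - 0.5) * 6 - (X[:, 1] - 0.5) * 4
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / n
        lambdas = lam_max * np.array([0.5, 0.1, 0.02])
        coefs, icepts = l1_logistic_path(X, y, lambdas, tol=1e-9)

        np.savetxt(tmp_path / "X.csv", X, delimiter=",")
        np.savetxt(tmp_path / "y.csv", y)
        np.savetxt(tmp_path / "lam.csv", lambdas)
        script = tmp_path / "cmp.R"
        script.write_text(
            'library(glmnet)\n'
            'X <- as.matrix(read.csv("X.csv", header=FALSE))\n'
            'y <- scan("y.csv")\n'
            'lam <- scan("lam.csv")\n'
            'f <- glmnet(X, y, family="binomial", alpha=1, lambda=lam,\n'
            '            standardize=FALSE, thresh=1e-14, maxit=1e6)\n'
            'co <- as.matrix(coef(f, s=lam))\n'
            'write.csv(co, "glmnet_coef.csv")\n'
        )
        subprocess.run(
            ["Rscript", script.name], cwd=tmp_path, check=True, capture_output=True
        )
        import pandas as pd

        g = pd.read_csv(tmp_path / "glmnet_coef.csv", index_col=0).to_numpy()
        for k in range(len(lambdas)):
            mine = np.concatenate([[icepts[k]], coefs[k]])
            np.testing.assert_allclose(mine, g[:, k], atol=1e-6)
            assert np.sum(coefs[k] != 0) == np.sum(g[1:, k] != 0)
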