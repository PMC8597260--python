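import dataclasses

import numpy as np
import pandas as pd
import pytest

from ternmeth import BetaMatrix, SampleSheet, ScoreModel, SyntheticConfig, generate


@pytest.fixture
def toy_beta() -> BetaMatrix:
    return BetaMatrix(
        pd.DataFrame(
            [[0.1, 0.5, 0.9], [0.2, 0.4, 0.8]],
            index=["cgA", "cgB"],
            columns=["s1", "s2", "s3"],
        )
    )


@pytest.fixture
def identity_model() -> ScoreModel:
    return ScoreModel("ahrr-like", [("cgA", 1.0)])


@pytest.fixture(scope="session")
def default_cohort():
    """One balanced 600-sample simulated cohort shared across tests."""
    cfg = dataclasses.replace(SyntheticConfig(), seed=7)
    return generate(cfg)


@pytest.fixture(scope="session")
def small_labelled_matrix():
    """Tiny two-class matrix for fast feature-selection tests.

    60 samples x 25 CpGs, 3 informative (persistent shift 0.2).
    """
    cfg = SyntheticConfig(
        n_current=30,
        n_former=0,
        n_never=30,
        n_persistent=3,
        n_reverting=0,
        n_partial=0,
        n_null=22,
        effect_persistent=0.2,
        baseline_range=(0.25, 0.75),
        noise_sd=0.5,
        seed=21,
    )
    beta, sheet, truth = generate(cfg)
    y = sheet.status().isin(["current", "former"]).to_numpy()
    return beta, y, truth
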