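"""Shared fixtures: small deterministic datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from pyropattern import (
    CohortParams,
    ExpressionMatrix,
    PYROPTOSIS_PANEL,
    generate_cohort,
    pair_features,
    train_classifier,
)


@pytest.fixture(scope="session")
def default_cohort():
    """One default two-subtype cohort (77 + 55 samples, 40 panel genes)."""
    return generate_cohort(CohortParams(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A faster 25 + 20 cohort for tests that only need the structure."""
    return generate_cohort(CohortParams(n_c1=25, n_c2=20, seed=5))


@pytest.fixture(scope="session")
def trained_model(default_cohort):
    """A pair-feature classifier trained on the default cohort's truth."""
    expr, _, truth = default_cohort
    feats = pair_features(expr, PYROPTOSIS_PANEL)
    model = train_classifier(feats, truth, n_trees=200, seed=3)
    return model, feats, truth


@pytest.fixture()
def random_expr():
    rng = np.random.default_rng(42)
    genes = [f"G{i}" for i in range(10)]
    samples = [f"S{i}" for i in range(20)]
    return ExpressionMatrix(
        pd.DataFrame(rng.normal(6, 2, (10, 20)), index=genes, columns=samples)
    )
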