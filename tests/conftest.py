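import numpy as np
import pandas as pd
import pytest

from subtelomics import GeneratorConfig, generate_cohort
from subtelomics.io import EXPRESSION, METHYLATION, OmicsMatrix


SMALL_COHORT_SEED = 20240915


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size synthetic cohort at the default study conditions."""
    return generate_cohort(GeneratorConfig(seed=SMALL_COHORT_SEED))


@pytest.fixture(scope="session")
def tiny_config():
    """A fast, valid configuration for determinism / plumbing tests."""
    return dict(
        n_low=8,
        n_high=8,
        chromosomes=(("chr1", 40_000_000), ("chr2", 30_000_000)),
        n_meth_probes=200,
        n_expr_probes=200,
        n_planted_de=3,
    )


@pytest.fixture
def expr_matrix():
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        rng.normal(2.0, 0.5, size=(6, 8)),
        index=[f"P{i}" for i in range(6)],
        columns=[f"S{i}" for i in range(8)],
    )
    return OmicsMatrix(EXPRESSION, values)


@pytest.fixture
def meth_matrix():
    rng = np.random.default_rng(8)
    values = pd.DataFrame(
        rng.uniform(0.05, 0.95, size=(6, 8)),
        index=[f"P{i}" for i in range(6)],
        columns=[f"S{i}" for i in range(8)],
    )
    return OmicsMatrix(METHYLATION, values)
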