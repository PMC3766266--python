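import numpy as np
import pandas as pd
import pytest

from ntsig.matrix import ExpressionMatrix
from ntsig.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One-dataset cohort, default effects, 80 samples, reduced gene count."""
    cfg = SimConfig(n_genes=400, n_datasets=1, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Two-dataset cohort at the default study conditions."""
    return generate_cohort(SimConfig(seed=7))


@pytest.fixture()
def toy_matrix():
    """Single gene, two groups of three with an obvious difference."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 5.0, 6.0, 7.0]], index=["g1"], columns=list("abcdef")
    )
    return ExpressionMatrix(values, id_level="gene")


@pytest.fixture()
def random_matrix():
    rng = np.random.default_rng(42)
    genes = [f"g{i:03d}" for i in range(60)]
    samples = [f"s{i:02d}" for i in range(12)]
    values = pd.DataFrame(rng.normal(8, 2, size=(60, 12)), index=genes, columns=samples)
    return ExpressionMatrix(values, id_level="gene")
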