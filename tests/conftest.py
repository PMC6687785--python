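import numpy as np
import pandas as pd
import pytest

from tumormatch.simulate import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The standard synthetic cohort: 2000 genes, 100 tumors, 30 cell lines,
    immune contamination on, seed 1."""
    return generate_cohort(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort for unit tests of downstream stages."""
    cfg = SyntheticConfig(
        n_genes=400,
        n_tumors=40,
        n_cell_lines=12,
        n_subtypes=2,
        n_marker_genes_per_subtype=15,
        n_immune_genes=40,
        n_proliferation_genes=15,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_matrix():
    """6 genes x 3 samples of small counts with exact hand-checkable values."""
    return pd.DataFrame(
        {
            "s1": [0.0, 2, 4, 6, 8, 10],
            "s2": [1.0, 3, 5, 7, 9, 11],
            "s3": [0.0, 0, 6, 12, 18, 24],
        },
        index=[f"g{i}" for i in range(1, 7)],
    )
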