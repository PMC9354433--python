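import numpy as np
import pytest

from mrs.feature_io import COUNTS, RELATIVE_ABUNDANCE, FeatureTable
from mrs.synthetic_data import default_spec, simulate_microbiome


@pytest.fixture
def rel_table():
    """3 taxa x 4 samples, columns sum to 1."""
    values = np.array(
        [
            [0.2, 0.5, 0.0, 1.0],
            [0.3, 0.25, 0.0, 0.0],
            [0.5, 0.25, 1.0, 0.0],
        ]
    )
    return FeatureTable(["A", "B", "C"], ["s1", "s2", "s3", "s4"], values, RELATIVE_ABUNDANCE)


@pytest.fixture
def counts_table():
    values = np.array(
        [
            [2.0, 5.0, 0.0, 9.0],
            [3.0, 0.0, 0.0, 1.0],
            [5.0, 5.0, 7.0, 0.0],
        ]
    )
    return FeatureTable(["A", "B", "C"], ["s1", "s2", "s3", "s4"], values, COUNTS)


@pytest.fixture(scope="session")
def small_cohort():
    """30+30 samples, 50 taxa, default signal structure: quick pipeline fixture."""
    return simulate_microbiome(default_spec(seed=11, n_cases=30, n_controls=30, n_taxa=50))
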