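import numpy as np
import pandas as pd
import pytest

from phenolink.core_data import CATEGORICAL, NUMERICAL, ExpressionMatrix, PhenotypeTable
from phenolink.fixtures import FixtureSpec, generate_cohort


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 samples x 2 features with one missing entry."""
    data = pd.DataFrame(
        [[1.0, 2.0], [np.nan, 4.0], [5.0, 6.0]],
        index=["S1", "S2", "S3"],
        columns=["ALB", "TF"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def binary_phenotypes() -> PhenotypeTable:
    data = pd.DataFrame(
        {
            "Pathological_Status": ["Tumor", "Tumor", "Non-Tumor", "Non-Tumor"],
            "Grade": [3.0, 2.0, 1.0, 1.0],
        },
        index=["S1", "S2", "S3", "S4"],
    )
    return PhenotypeTable(data, {"Pathological_Status": CATEGORICAL, "Grade": NUMERICAL})


@pytest.fixture(scope="session")
def default_cohort():
    """Seeded 20-vs-20 cohort, 1000 features, 10% planted DE at |log2FC|=1."""
    return generate_cohort(FixtureSpec(seed=0, n_qc_replicates=0))


@pytest.fixture(scope="session")
def small_cohort():
    """Quick cohort for pipeline tests: 10 vs 10, 120 features, QC + missing."""
    spec = FixtureSpec(
        n_per_group=10, n_features=120, frac_de=0.1, missing_rate=0.05,
        n_qc_replicates=3, seed=5,
    )
    return spec, generate_cohort(spec)
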