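import numpy as np
import pandas as pd
import pytest

from ecplsc import CohortSpec, build_design, generate_cohort


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """The 128-subject cohort at its default composition."""
    return generate_cohort(CohortSpec(seed=42))


@pytest.fixture(scope="session")
def default_design(default_cohort):
    return build_design(default_cohort)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 24-subject cohort for cheap tests."""
    return generate_cohort(
        CohortSpec(n_subjects=24, n_carriers=10, n_symptomatic=9, n_regions=20,
                   n_timepoints=60, seed=7)
    )


def random_correlation_matrix(n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample correlation matrix of random Gaussian data (full rank, PSD)."""
    data = rng.standard_normal((n, 4 * n))
    corr = np.corrcoef(data)
    np.fill_diagonal(corr, 1.0)
    return corr
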