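import numpy as np
import pytest

from fibropsi.preprocess import preprocess_matrix
from fibropsi.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """20 CG + 20 FG triplicate cohort with planted case peaks at 301/579."""
    config = CohortConfig(n_control=20, n_case=20, seed=1)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def preprocessed_small(small_cohort):
    matrix, _, _ = small_cohort
    return preprocess_matrix(matrix)


@pytest.fixture(scope="session")
def separable_1d():
    """Two well-separated 1-D Gaussian classes with known sample stats."""
    rng = np.random.default_rng(42)
    x0 = rng.normal(0.0, 1.0, 60)
    x1 = rng.normal(6.0, 1.0, 60)
    X = np.concatenate([x0, x1])[:, None]
    y = np.array(["CG"] * 60 + ["FG"] * 60, dtype=object)
    return X, y
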