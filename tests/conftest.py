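import numpy as np
import pandas as pd
import pytest

from ileum_integrate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Default-model cohort, shrunk probe count for speed."""
    return generate_cohort(CohortConfig(n_probes=60, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def random_matrix(rng):
    """Probes x samples matrix with two balanced classes, no signal."""
    values = pd.DataFrame(
        rng.normal(size=(50, 12)),
        index=[f"p{i}" for i in range(50)],
        columns=[f"s{i}" for i in range(12)],
    )
    labels = ["A"] * 6 + ["B"] * 6
    return values, labels
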