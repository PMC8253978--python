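import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from reostrat import ExpressionMatrix, SyntheticSpec, generate_cohorts

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """5 genes x 4 samples with easy hand-checkable values."""
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [5.0, 5.0, 5.0, 5.0],
         [0.5, 0.5, 0.5, 0.5],
         [10.0, 1.0, 10.0, 1.0],
         [2.0, 8.0, 4.0, 6.0]],
        index=["gA", "gB", "gC", "gD", "gE"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(df)


@pytest.fixture(scope="session")
def tiny_study():
    """Small two-cohort, three-subtype synthetic study (session-cached)."""
    spec = SyntheticSpec(
        n_genes=400, n_marker_genes_per_subtype=20,
        samples_per_subtype={"A": {"1": 30, "2": 30, "3": 30},
                             "B": {"1": 20, "2": 20, "3": 20}},
        seed=11,
    )
    return spec, generate_cohorts(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
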