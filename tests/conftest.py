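import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from prosonet import AttributedNetwork

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_attributes(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Random complete attribute table on n nodes (ids n000...)."""
    return pd.DataFrame(
        {
            "prosociality": rng.integers(8, 41, n) / 8.0,  # multiples of 1/8 in [1,5]
            "sex": rng.integers(0, 2, n),
            "income": rng.integers(1, 6, n).astype(float),
            "father_education": rng.integers(1, 10, n).astype(float),
        },
        index=pd.Index([f"n{i:03d}" for i in range(n)], name="id"),
    )


def make_network(n: int, density: float, rng: np.random.Generator) -> AttributedNetwork:
    A = rng.random((n, n)) < density
    np.fill_diagonal(A, False)
    return AttributedNetwork([f"n{i:03d}" for i in range(n)], A, make_attributes(n, rng))


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def net_factory():
    return make_network


@pytest.fixture
def attrs_factory():
    return make_attributes
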