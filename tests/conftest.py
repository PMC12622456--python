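import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ubiflow import AbundanceMatrix, SampleDesign

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[
        HealthCheck.too_slow,
        # design fixtures are frozen dataclasses, safe to share across examples
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("default")


@pytest.fixture
def design_4v4() -> SampleDesign:
    samples = [f"Ctrl_{i}" for i in range(1, 5)] + [f"HLU_{i}" for i in range(1, 5)]
    return SampleDesign(
        tuple(samples),
        {s: s.split("_")[0] for s in samples},
        ("Ctrl", "HLU"),
    )


def make_matrix(values, design, scale="raw", feature_prefix="F"):
    """Small AbundanceMatrix from a 2-D array-like (features x samples)."""
    arr = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        arr,
        index=[f"{feature_prefix}{i}" for i in range(arr.shape[0])],
        columns=list(design.sample_ids),
    )
    return AbundanceMatrix(df, scale=scale)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
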