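import numpy as np
import pytest
from hypothesis import settings

import taafgex as tg

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(
    n_samples=30,
    n_landmarks=4,
    n_targets=6,
    seed=0,
    series=None,
    phenotype=None,
):
    """Small random ExpressionDataset for structural tests."""
    r = np.random.default_rng(seed)
    values = r.standard_normal((n_samples, n_landmarks + n_targets))
    return tg.ExpressionDataset(
        values=values,
        sample_ids=[f"s{i:03d}" for i in range(n_samples)],
        gene_ids=[f"L{j}" for j in range(n_landmarks)]
        + [f"T{j}" for j in range(n_targets)],
        gene_role=["landmark"] * n_landmarks + ["target"] * n_targets,
        series_label=series,
        phenotype=phenotype,
    )


@pytest.fixture
def small_dataset():
    return make_dataset()
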