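import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mettrial import TrialDataset, PlotConfig, make_fixture

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def tiny_balanced() -> TrialDataset:
    return make_fixture("tiny_balanced")


@pytest.fixture
def zero_noise() -> TrialDataset:
    return make_fixture("zero_noise")


@pytest.fixture(scope="session")
def sparse_like_paper() -> TrialDataset:
    return make_fixture("sparse_like_paper")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_rcbd_dataset(rng: np.random.Generator, g: int, r: int, env: str = "E1") -> TrialDataset:
    """One-environment RCBD with arbitrary continuous values, for oracle tests."""
    rows = []
    for i in range(g):
        for k in range(r):
            rows.append(
                {
                    "environment": env,
                    "genotype": f"G{i + 1}",
                    "replicate": f"R{k + 1}",
                    "grain_yield_t_ha": float(rng.normal(5.0, 2.0)) + i * rng.uniform(0, 1),
                }
            )
    return TrialDataset(pd.DataFrame(rows), plot_config=PlotConfig(npa_m2=8.0))
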