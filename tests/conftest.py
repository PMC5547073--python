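import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from entronet import (
    PipelineConfig,
    SyntheticSpec,
    paired_timeseries_dataset,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Scaled-down paired study: 3 subjects, 40 regions, 4 modules."""
    return SyntheticSpec(
        n_subjects=3,
        n_regions=40,
        n_modules=4,
        n_volumes=120,
        dispersion_after=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return paired_timeseries_dataset(small_spec)


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    # above the N=40 sparsity floor (8) and high enough for connected graphs
    return PipelineConfig(k_min=16, k_max=19, null_size=5, seed=5)


def random_network_factory(rng: np.random.Generator, n_max: int = 12):
    """Random simple graph with 2 <= N <= n_max and random density."""
    from entronet import Network

    n = int(rng.integers(2, n_max + 1))
    p = rng.uniform(0.1, 0.9)
    iu = [(i, j) for i in range(n) for j in range(i + 1, n)]
    edges = [e for e in iu if rng.random() < p]
    return Network.from_edges(n, edges)
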