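import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_pedigree():
    from sirethresh.simulator import build_pedigree

    return build_pedigree(5, 10, 2, seed=11)


@pytest.fixture
def small_dataset(small_pedigree):
    """A small mixed dataset with a handful of ECP classes."""
    from sirethresh.simulator import simulate_dataset

    ds, truth = simulate_dataset(
        small_pedigree, 300, 12, (-2.5, 0.6), 0.05, seed=21
    )
    return ds, truth
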