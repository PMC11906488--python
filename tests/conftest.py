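import numpy as np
import pytest

from idsim import (
    DFEConfig,
    RegionSpec,
    ScenarioConfig,
    make_fixture,
    run_simulation,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def hwe_matrix():
    return make_fixture("hwe-20x50", seed=1)


@pytest.fixture(scope="session")
def small_run():
    """A small but non-trivial finished simulation shared across tests."""
    cfg = ScenarioConfig(
        N=100,
        generations=300,
        U_neutral=1.37,
        U_deleterious=0.07,
        U_overdominant=0.002,
        seed=7,
        region=RegionSpec.uniform(10_000_000, 100.0),
        name="shared-small",
    )
    return run_simulation(cfg, DFEConfig())


@pytest.fixture(scope="session")
def small_matrix(small_run):
    return small_run.export_neutral_genotypes()
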