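import numpy as np
import pytest

from selfpoly.pipeline import make_fixture
from selfpoly.simulate import SimulationConfig, run


@pytest.fixture
def rng():
    return np.random.default_rng(20240717)


@pytest.fixture(scope="session")
def tiny_run():
    """One small simulation shared by tests that only inspect its outputs."""
    cfg = SimulationConfig.desk_scale(
        N=60, L=50_000, burn_in=300, post_gens=120,
        stats_interval_pre=100, stats_interval_post=40,
        sample_offsets=(40, 120))
    return run(cfg, seed=11)


@pytest.fixture
def hwe_pop():
    return make_fixture("hwe_single_locus")


@pytest.fixture
def inbred_pop():
    return make_fixture("inbred_single_locus")


@pytest.fixture
def negative_ld_pop():
    return make_fixture("negative_ld_pair")
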