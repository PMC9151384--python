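import numpy as np
import pytest

from starimpute import simdata, stars


@pytest.fixture(scope="session")
def allele_table():
    return stars.load_default_definitions()


@pytest.fixture(scope="session")
def bins():
    return stars.load_default_bins()


TINY_SIM = dict(
    n_panel_haplotypes=120,
    n_target_samples=20,
    n_sites=60,
    founder_count=12,
    del_hap_freq=0.05,
    dup_hap_freq=0.10,
    genotype_error=0.0,
    seed=7,
)


@pytest.fixture(scope="session")
def tiny_study():
    """Small simulated study reused across fast tests."""
    return simdata.simulate_study(simdata.SimConfig(**TINY_SIM))


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
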