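import numpy as np
import pytest

from cemag.simulate import SimConfig, make_pathway_catalog, simulate_genome


@pytest.fixture(scope="session")
def catalog():
    return make_pathway_catalog(seed=1)


@pytest.fixture(scope="session")
def small_config():
    # short contigs keep unit tests quick; genes still fit comfortably
    return SimConfig(seed=5, n_genomes_per_group=2, contig_length=12_000, n_contigs=3)


@pytest.fixture(scope="session")
def ice_genome(catalog, small_config):
    """One intermediate-chain-elongator genome with its truth record."""
    rng = np.random.default_rng(42)
    return simulate_genome("intermediate_ce", catalog, small_config,
                           genome_id="ICE1", rng=rng)
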