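import numpy as np
import pytest
from hypothesis import settings

from lacfam.simulate import SimConfig, build_family_fixture

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_fixture():
    """A compact family fixture exercising every generator feature."""
    cfg = SimConfig(
        seed=17,
        n_chromosomes=2,
        chrom_length_bp=3_000_000,
        n_family_genes=12,
        n_decoy_genes=6,
        tandem_arrays=((3, 5_000), (2, 8_000)),
        segmental_pairs=2,
        n_redundant_loci=3,
        n_partial_decoys=2,
    )
    return build_family_fixture(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
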