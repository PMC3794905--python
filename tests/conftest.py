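import numpy as np
import pytest

from chromstates import synthgenome as sg


@pytest.fixture(scope="session")
def small_genome():
    """A compact full synthetic genome (2 chromosomes x 400 windows) with
    genes, sequence and U-domains, shared across characterization tests."""
    spec = sg.default_spec(n_chromosomes=2, windows_per_chromosome=400)
    return sg.generate_udomain_genome(spec, seed=11)


@pytest.fixture(scope="session")
def default_genome():
    """The default-scale genome (4 x 5000 windows) without genes/sequence,
    used by the segmentation-recovery and conservation tests."""
    spec = sg.default_spec()
    return sg.generate_udomain_genome(spec, seed=7, with_genes=False, with_sequence=False)


@pytest.fixture(scope="session")
def default_segmentation(default_genome):
    from chromstates import statefinder as sf

    return sf.segment(default_genome.mark_matrix, default_genome.mark_names, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
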