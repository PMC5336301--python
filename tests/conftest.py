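import numpy as np
import pytest

from mitoribomap import (
    default_masks,
    find_restriction_sites,
    synthetic_reference,
)
from mitoribomap.mtgenome import MtGenome


@pytest.fixture(scope="session")
def genome():
    """Synthetic rCRS-like reference: 16,569 bp, C-rich forward strand
    (forward = L), exactly 11 HincII sites."""
    return synthetic_reference(seed=2020)


@pytest.fixture(scope="session")
def sites(genome):
    return find_restriction_sites(genome)


@pytest.fixture(scope="session")
def mask(genome, sites):
    return default_masks(genome, sites)


@pytest.fixture()
def toy_genome():
    """Small random circular genome for oracle-style tests."""
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    return MtGenome(name="toy2k", sequence=seq)
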