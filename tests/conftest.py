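import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from panlin.sequence_io import SeqRecord
from panlin.synthetic_data import SyntheticPangenomeSpec, random_protein, simulate_pangenome

AA20 = "ACDEFGHIKLMNPQRSTVWY"
NT4 = "ACGT"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_protein(rng, length, **kw):
    return SeqRecord(seq=random_protein(rng, length), moltype="aa", **kw)


@pytest.fixture(scope="session")
def small_pangenome():
    """A 5-genome synthetic pangenome with recoverable structure, shared by
    clustering/pangenome/acceptance tests (generation is the slow part)."""
    spec = SyntheticPangenomeSpec(
        n_genomes=5, n_core=20, n_accessory=8, n_unique_per_genome=[2, 4, 6, 8, 10],
        within_family_divergence=0.05, protein_length_range=(80, 160), seed=11)
    return simulate_pangenome(spec)
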