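import numpy as np
import pytest

from submap.models import build_jc, build_t92, register_gc
from submap.phylio import Alignment, codon_alphabet, nucleotide_alphabet, read_newick


@pytest.fixture(scope="session")
def nt_alphabet():
    return nucleotide_alphabet()


@pytest.fixture(scope="session")
def codon61():
    return codon_alphabet()


@pytest.fixture(scope="session")
def jc4():
    return build_jc()


@pytest.fixture(scope="session")
def t92_model():
    return build_t92(2.0, 0.7)


@pytest.fixture(scope="session")
def gc_register(nt_alphabet):
    return register_gc(nt_alphabet)


@pytest.fixture
def tree4():
    return read_newick("((A:0.1,B:0.2):0.15,(C:0.12,D:0.3):0.1);")


@pytest.fixture
def aln4(nt_alphabet):
    return Alignment.from_sequences(
        nt_alphabet, [("A", "ACGT"), ("B", "AGGT"), ("C", "TCGA"), ("D", "ACGT")])


def random_nt_alignment(rng, taxa, n_sites):
    return Alignment.from_sequences(
        nucleotide_alphabet(),
        [(t, "".join(rng.choice(list("ACGT"), size=n_sites))) for t in taxa])


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
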