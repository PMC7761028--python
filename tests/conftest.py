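import numpy as np
import pytest

from wrkymine.seqio import SequenceRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return np.random.default_rng(20)


def random_protein(rng, n, alphabet=AA20):
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), n)])


def random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture
def protein_record():
    def make(residues, rec_id="p1"):
        return SequenceRecord(rec_id, residues, "protein")
    return make
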