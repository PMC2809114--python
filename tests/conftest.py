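import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from batrh1.codonseq import CodonAlignment, standard_code


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture
def toy_alignment():
    """3 taxa x 2 codons differing only by one synonymous third-position change."""
    return CodonAlignment(
        ["t1", "t2", "t3"],
        ["ATGGGA", "ATGGGA", "ATGGGG"],
    )


def make_alignment(taxa_seqs):
    return CodonAlignment(list(taxa_seqs), [taxa_seqs[t] for t in taxa_seqs])


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def random_codon_seq(rng, n_codons, code):
    sense = code.sense_codons
    return "".join(sense[i] for i in rng.integers(0, len(sense), size=n_codons))
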