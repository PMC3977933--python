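import numpy as np
import pytest

from gridmsa.fastlsa import SequencePairScorer
from gridmsa.generate import random_family
from gridmsa.io_formats import Alphabet, SequenceRecord
from gridmsa.scoring import ScoringScheme

DNA = "ACGT"


def random_dna(rng, length):
    return "".join(rng.choice(list(DNA), size=length))


def make_record(rid, residues, alphabet=Alphabet.DNA):
    return SequenceRecord(rid, rid, residues, alphabet)


def make_scorer(a, b, scheme):
    return SequencePairScorer(scheme.encode(a), scheme.encode(b),
                              scheme.int_matrix, scheme.int_gap_open,
                              scheme.int_gap_extend)


def oracle_inputs(a, b, scheme):
    """The (sub, goa, gea, gob, geb) grids the reference aligner consumes."""
    ca, cb = scheme.encode(a), scheme.encode(b)
    m = scheme.int_matrix
    sub = [[int(m[ca[i], cb[j]]) for j in range(len(b))]
           for i in range(len(a))]
    go, ge = scheme.int_gap_open, scheme.int_gap_extend
    return (sub, [go] * len(a), [ge] * len(a), [go] * len(b), [ge] * len(b))


@pytest.fixture(scope="session")
def dna_scheme():
    return ScoringScheme.dna()


@pytest.fixture(scope="session")
def simple_scheme():
    """match +1 / mismatch -1, open 2, extend 0.5."""
    return ScoringScheme.dna(match=1.0, mismatch=-1.0, gap_open=2.0,
                             gap_extend=0.5)


@pytest.fixture(scope="session")
def small_family():
    return random_family(n=6, length=250, sub_rate=0.05, indel_rate=0.01,
                         seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)
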