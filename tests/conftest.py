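import pytest

from redexome.catalogue import default_catalogue
from redexome.simulate import SimRead, ReadEvidence


@pytest.fixture(scope="session")
def catalogue():
    return default_catalogue()


@pytest.fixture(scope="session")
def by_gene(catalogue):
    return {locus.gene: locus for locus in catalogue}


def make_evidence(sample_id="S1", gene="HTT", read_length=150, reads=()):
    return ReadEvidence(sample_id, gene, read_length, list(reads))


def spanning(units, motif="CAG", hq=True):
    return SimRead("spanning", motif * units, hq, implied_units=units)


def flanking(observed_units, motif="CAG", hq=True):
    return SimRead(
        "flanking", motif * observed_units, hq, implied_min_units=observed_units
    )


def in_repeat(read_length, motif="CAG", hq=True, sequence=None):
    seq = sequence if sequence is not None else (motif * read_length)[:read_length]
    return SimRead(
        "in_repeat", seq, hq, implied_min_units=read_length // len(motif)
    )
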