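import numpy as np
import pytest

from mitobarcode.seqio import Alignment, SequenceRecord


@pytest.fixture
def make_alignment():
    def _make(seqs, species=None, ids=None):
        records = []
        for i, s in enumerate(seqs):
            records.append(SequenceRecord(
                id=ids[i] if ids else f"seq{i}",
                seq=s,
                species=species[i] if species else "Testus exempli",
            ))
        return Alignment(records)
    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_dna(rng, length, p=(0.25, 0.25, 0.25, 0.25)):
    return "".join(rng.choice(list("ACGT"), size=length, p=list(p)))
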