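import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from hormobind import (LabeledDataset, SequenceRecord, POSITIVE, NEGATIVE,
                       write_fasta)


@pytest.fixture
def tiny_records():
    return [
        SequenceRecord("p1", "ACDEFGHIKL", POSITIVE),
        SequenceRecord("p2", "MNPQRSTVWY", POSITIVE),
        SequenceRecord("n1", "AAAACCCCDD", NEGATIVE),
        SequenceRecord("n2", "LLLLKKKKSS", NEGATIVE),
    ]


@pytest.fixture
def tiny_dataset(tiny_records):
    return LabeledDataset(records=tiny_records)


@pytest.fixture
def fasta_pair(tmp_path, tiny_records):
    pos = tmp_path / "pos.fasta"
    neg = tmp_path / "neg.fasta"
    write_fasta([r for r in tiny_records if r.label == POSITIVE], pos)
    write_fasta([r for r in tiny_records if r.label == NEGATIVE], neg)
    return pos, neg


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
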