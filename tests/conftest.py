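import numpy as np
import pytest

from coihap.seqio import Alignment, SequenceRecord


@pytest.fixture
def f1() -> Alignment:
    """The hand-enumerated diversity fixture: n=4, L=8, S=2, k=1.0."""
    seqs = ["ACGTACGT", "ACGTACGA", "ACGAACGT", "ACGTACGT"]
    return Alignment([SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs, 1)])


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


def random_alignment(rng, n=8, L=30, ids=None) -> Alignment:
    """Random ACGT alignment helper for property tests."""
    mat = rng.integers(0, 4, size=(n, L))
    seqs = ["".join("ACGT"[b] for b in row) for row in mat]
    ids = ids or [f"r{i}" for i in range(n)]
    return Alignment([SequenceRecord(i, s) for i, s in zip(ids, seqs)])
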