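import numpy as np
import pytest

from srnapipe.seq_io import Read, ReferenceRecord, ReferenceSet


@pytest.fixture
def rng():
    return np.random.default_rng(20140305)


@pytest.fixture
def random_refs(rng):
    """20 random references spanning mature-miRNA to genome-slice lengths."""
    bases = np.array(list("ACGT"))
    return ReferenceSet([
        ReferenceRecord(f"ref{i:02d}", "".join(rng.choice(bases, int(rng.integers(18, 91)))))
        for i in range(20)
    ])


def make_read(read_id: str, bases: str, q: int = 30) -> Read:
    return Read(read_id, bases, tuple([q] * len(bases)))


@pytest.fixture
def mk_read():
    return make_read
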