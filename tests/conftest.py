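import numpy as np
import pytest

from wildtrie import SeqRecord

_BASES = np.array(list("ACGT"))


def make_instance(rng, n, length, wc_frac, n_parents=None):
    """A random read set with duplicate structure.

    Reads are drawn with replacement from a small parent pool, then each base
    is independently masked to 'N' with probability ``wc_frac`` — so reads
    carry variable wildcard counts, unlike the fixed-count simulator.
    """
    n_parents = n_parents or max(1, n // 3)
    parents = ["".join(rng.choice(_BASES, size=length)) for _ in range(n_parents)]
    records = []
    for i in range(n):
        chars = list(parents[rng.integers(n_parents)])
        for j in range(length):
            if rng.random() < wc_frac:
                chars[j] = "N"
        records.append(SeqRecord(f"r{i}", "".join(chars), input_rank=i))
    return records


@pytest.fixture
def rng():
    return np.random.default_rng(20240418)


@pytest.fixture
def toy_records():
    """The three-read toy whose equivalence graph is the path TAC - TNC - TGC."""
    return [
        SeqRecord("r0", "TAC", input_rank=0),
        SeqRecord("r1", "TNC", input_rank=1),
        SeqRecord("r2", "TGC", input_rank=2),
    ]
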