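import numpy as np
import pytest

from invscan.records import SequenceRecord, revcomp


def random_seq(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def toy_triple():
    """Target X·Y·Z vs query X·revcomp(Y)·Z with 200-bp repeat-free segments."""
    x, y, z = random_seq(200, 11), random_seq(200, 12), random_seq(200, 13)
    target = SequenceRecord(id="t", seq=x + y + z)
    query = SequenceRecord(id="q", seq=x + revcomp(y) + z)
    return query, target
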