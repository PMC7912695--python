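import numpy as np
import pytest

from desertam.readproc import ReadPair


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def make_pair(fwd_seq, rev_seq, q=35, pair_id="r1", site="S"):
    """Read pair with flat qualities."""
    return ReadPair(
        id=pair_id,
        fwd_seq=fwd_seq, fwd_qual=[q] * len(fwd_seq),
        rev_seq=rev_seq, rev_qual=[q] * len(rev_seq),
        site=site,
    )
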