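import numpy as np
import pytest

from trimux.intervals import GenomicInterval, IntervalSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_interval_set(rng, n, chroms=("chr1", "chr2"), max_pos=10_000,
                        max_len=500):
    ivs = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        ivs.append(GenomicInterval(str(rng.choice(chroms)), start, start + length))
    return IntervalSet(ivs)
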