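import numpy as np
import pytest

from chromalink import Anchor, GenomicInterval, Loop, LoopSet, Peak, PeakSet


def make_peakset(triples, factor="F", condition=""):
    """PeakSet from (chrom, start, end) triples."""
    return PeakSet(
        factor,
        condition,
        [Peak(GenomicInterval(c, s, e), name=f"{factor}_{i}") for i, (c, s, e) in enumerate(triples)],
    )


def make_loopset(pairs, condition=""):
    """LoopSet from ((chrom,start,end), (chrom,start,end)) anchor pairs."""
    return LoopSet(
        condition,
        [
            Loop(
                Anchor(GenomicInterval(*a), 1),
                Anchor(GenomicInterval(*b), 2),
                loop_id=f"L{i}",
            )
            for i, (a, b) in enumerate(pairs)
        ],
    )


def random_intervals(rng, n, n_chrom=2, max_pos=10_000, max_width=300):
    """n random (chrom, start, end) triples."""
    out = []
    for _ in range(n):
        chrom = f"chr{rng.integers(1, n_chrom + 1)}"
        start = int(rng.integers(0, max_pos))
        width = int(rng.integers(1, max_width))
        out.append((chrom, start, start + width))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
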