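import numpy as np
import pytest

from backsplice.model import AlignmentSegment, DetectorConfig, parse_cigar


def make_seg(
    cigar,
    pos=1000,
    ref="chrA",
    strand="+",
    read_id="r1",
    mapq=60,
    mate_index=1,
    seq=None,
    **kw,
):
    return AlignmentSegment(
        read_id=read_id,
        ref=ref,
        pos=pos,
        strand=strand,
        cigar=parse_cigar(cigar) if isinstance(cigar, str) else tuple(cigar),
        mapq=mapq,
        mate_index=mate_index,
        seq=seq,
        **kw,
    )


@pytest.fixture
def seg_factory():
    return make_seg


@pytest.fixture
def cfg():
    return DetectorConfig(stringency="low")


def random_genome(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


@pytest.fixture
def rng():
    return np.random.default_rng(42)
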