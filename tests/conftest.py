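from __future__ import annotations

import pytest

from cutscope.amplicon import AmpliconRef, clear_alignment_cache
from cutscope.digenome import AlignmentRecord
from cutscope.synthdata import demo_amplicon, simulate_genome


def fwd(start: int, length: int = 50, contig: str = "chr1") -> AlignmentRecord:
    return AlignmentRecord(contig, start, length, "+")


def rev(start: int, length: int = 50, contig: str = "chr1") -> AlignmentRecord:
    return AlignmentRecord(contig, start, length, "-")


def rev_ending_at(position: int, length: int = 50, contig: str = "chr1") -> AlignmentRecord:
    """Reverse-strand record whose 5' end (rightmost base) is ``position``."""
    return AlignmentRecord(contig, position - length + 1, length, "-")


@pytest.fixture(scope="session")
def demo_ref() -> AmpliconRef:
    seq, offset = demo_amplicon()
    return AmpliconRef(seq, offset)


@pytest.fixture(scope="session")
def toy_genome():
    return simulate_genome(1, 10_000, 0.5, seed=1)


@pytest.fixture(autouse=True)
def _fresh_alignment_cache():
    clear_alignment_cache()
    yield
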