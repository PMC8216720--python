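"""Editing-outcome quantification from amplicon deep sequencing.

Reads are median-quality filtered, globally aligned to the expected
amplicon, and classified as no-change / insertion / deletion from the
indel events falling inside a window around the start codon.  Downstream
summaries cover the per-category read counts, indel-size spectra, the base
composition of single insertions inside the start codon, and whether an
insertion recreates a translatable (cryptic) ATG with a favorable -3
context.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import Align, SeqIO

from .synthdata import IndelEvent

__all__ = [
    "AmpliconRef",
    "FastqRead",
    "ReadOutcome",
    "IndelSummary",
    "InsertionComposition",
    "KozakCall",
    "AlignmentResult",
    "read_fastq",
    "filter_reads_by_median_quality",
    "align_to_amplicon",
    "classify_read",
    "indel_summary",
    "size_spectrum",
    "insertion_base_composition",
    "kozak_assessment",
    "insertion_placement_range",
]


@dataclass(frozen=True)
class AmpliconRef:
    """The expected amplicon and the analysis window around its start codon."""

    sequence: str
    start_codon_offset: int
    window: int = 10  # bases either side of the start codon

    def __post_init__(self) -> None:
        o = self.start_codon_offset
        if self.sequence[o : o + 3] != "ATG":
            raise ValueError("no ATG at the stated start-codon offset")

    @property
    def target_window(self) -> tuple[int, int]:
        """0-based half-open reference interval in which events count."""
        lo = max(0, self.start_codon_offset - self.window)
        hi = min(len(self.sequence), self.start_codon_offset + 3 + self.window)
        return lo, hi


@dataclass(frozen=True)
class FastqRead:
    name: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(f"quality/sequence length mismatch in {self.name}")


@dataclass(frozen=True)
class ReadOutcome:
    """Classification of one read against the amplicon."""

    read_id: str
    category: str  # no_change | insertion | deletion | discarded
    events: tuple[IndelEvent, ...] = ()
    reason: str = ""  # set when discarded


@dataclass(frozen=True)
class IndelSummary:
    """Per-category read counts for one sample; percentages over retained."""

    total_reads: int
    n_no_change: int
    n_insertion: int
    n_deletion: int

    def __post_init__(self) -> None:
        if self.n_no_change + self.n_insertion + self.n_deletion != self.total_reads:
            raise ValueError("category counts do not sum to total reads")

    @classmethod
    def from_counts(
        cls, total: int, no_change: int, insertion: int, deletion: int
    ) -> "IndelSummary":
        return cls(total, no_change, insertion, deletion)

    @property
    def n_indel(self) -> int:
        return self.n_insertion + self.n_deletion

    def _pct(self, n: int) -> float:
        if self.total_reads == 0:
            raise ValueError("no retained reads")
        return 100.0 * n / self.total_reads

    @property
    def pct_no_change(self) -> float:
        return self._pct(self.n_no_change)

    @property
    def pct_insertion(self) -> float:
        return self._pct(self.n_insertion)

    @property
    def pct_deletion(self) -> float:
        return self._pct(self.n_deletion)

    @property
    def pct_indel(self) -> float:
        return self._pct(self.n_indel)


@dataclass(frozen=True)
class InsertionComposition:
    """Base counts of single insertions inside the start codon."""

    counts: dict[str, int]  # keys A, T, G, C

    @classmethod
    def from_counts(cls, a: int, t: int, g: int, c: int) -> "InsertionComposition":
        return cls({"A": a, "T": t, "G": g, "C": c})

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def percentage(self, base: str) -> float:
        if self.total == 0:
            raise ValueError("no qualifying single insertions")
        return 100.0 * self.counts[base] / self.total


@dataclass(frozen=True)
class KozakCall:
    cryptic_atg_present: bool
    new_atg_offset: int | None = None
    minus3_base: str | None = None

    @property
    def kozak_favorable(self) -> bool:
        return self.minus3_base in ("A", "G")


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    """Stream FASTQ records as :class:`FastqRead` (Phred+33 decoded)."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield FastqRead(
            name=rec.id,
            sequence=str(rec.seq).upper(),
            qualities=tuple(rec.letter_annotations["phred_quality"]),
        )


def filter_reads_by_median_quality(
    reads: Iterable[FastqRead], cutoff: float = 5.0
) -> tuple[list[FastqRead], list[tuple[str, float]]]:
    """Drop reads whose median per-base quality is <= ``cutoff``.

    The median of an even-length list is the mean of the two central order
    statistics.  Returns (retained, discard log of (name, median)).
    """
    retained: list[FastqRead] = []
    discarded: list[tuple[str, float]] = []
    for read in reads:
        med = statistics.median(read.qualities)
        if med <= cutoff:
            discarded.append((read.name, med))
        else:
            retained.append(read)
    return retained, discarded


@dataclass(frozen=True)
class AlignmentResult:
    """A global read-vs-amplicon alignment reduced to its indel events."""

    score: float
    events: tuple[IndelEvent, ...]  # left-normalized, reference coordinates
    ref_covered: tuple[int, int]  # reference span actually aligned to bases


def _left_normalize_deletion(ref: str, pos: int, length: int) -> int:
    while pos > 0 and ref[pos - 1] == ref[pos + length - 1]:
        pos -= 1
    return pos


def _left_normalize_insertion(ref: str, pos: int, bases: str) -> tuple[int, str]:
    while pos > 0 and ref[pos - 1] == bases[-1]:
        bases = bases[-1] + bases[:-1]
        pos -= 1
    return pos, bases


def insertion_placement_range(ref: str, pos: int, bases: str) -> tuple[int, int]:
    """Inclusive range of equivalent placements for a left-aligned insertion.

    An insertion can slide right through matching reference bases without
    changing the edited sequence; the returned (left, right) bounds are the
    canonical position and the rightmost equivalent one.
    """
    left = pos
    right = pos
    b = bases
    while right < len(ref) and ref[right] == b[0]:
        b = b[1:] + b[0]
        right += 1
    return left, right


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -6.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()
_CACHE: dict[tuple[str, str], AlignmentResult] = {}
_CACHE_MAX = 200_000


def align_to_amplicon(read: str, ref: AmpliconRef) -> AlignmentResult:
    """Globally align a read to the amplicon and extract its indel runs.

    Scoring: match +1, mismatch -2, gap open -6, gap extend -1.  Indels are
    reported in reference coordinates and left-aligned within homopolymers.
    Results are memoized by (reference, read) since amplicon libraries are
    dominated by a handful of distinct sequences.
    """
    if not read:
        raise ValueError("empty read")
    if len(read) < 20:
        raise ValueError("read shorter than 20 nt")
    key = (ref.sequence, read)
    cached = _CACHE.get(key)
    if cached is not None:
        return cached

    if read == ref.sequence:  # overwhelmingly the common case
        result = AlignmentResult(
            score=float(len(read)), events=(), ref_covered=(0, len(read))
        )
    else:
        aln = _ALIGNER.align(ref.sequence, read)[0]
        t_blocks, q_blocks = aln.aligned
        events: list[IndelEvent] = []
        # read overhang before the first aligned block = insertion at its start
        if len(q_blocks) and q_blocks[0][0] > 0:
            pos, bases = _left_normalize_insertion(
                ref.sequence, int(t_blocks[0][0]), read[: q_blocks[0][0]]
            )
            events.append(IndelEvent("ins", pos, len(bases), bases))
        for i in range(len(t_blocks) - 1):
            t_gap = int(t_blocks[i + 1][0] - t_blocks[i][1])
            q_gap = int(q_blocks[i + 1][0] - q_blocks[i][1])
            tpos = int(t_blocks[i][1])
            if t_gap > 0:
                pos = _left_normalize_deletion(ref.sequence, tpos, t_gap)
                events.append(IndelEvent("del", pos, t_gap))
            if q_gap > 0:
                bases = read[int(q_blocks[i][1]) : int(q_blocks[i + 1][0])]
                ins_at = tpos + t_gap
                pos, bases = _left_normalize_insertion(ref.sequence, ins_at, bases)
                events.append(IndelEvent("ins", pos, q_gap, bases))
        if len(q_blocks) and q_blocks[-1][1] < len(read):
            bases = read[int(q_blocks[-1][1]) :]
            pos, bases = _left_normalize_insertion(
                ref.sequence, int(t_blocks[-1][1]), bases
            )
            events.append(IndelEvent("ins", pos, len(bases), bases))
        covered = (
            (int(t_blocks[0][0]), int(t_blocks[-1][1]))
            if len(t_blocks)
            else (0, 0)
        )
        result = AlignmentResult(
            score=float(aln.score),
            events=tuple(sorted(events, key=lambda e: e.position)),
            ref_covered=covered,
        )
    if len(_CACHE) < _CACHE_MAX:
        _CACHE[key] = result
    return result


def _event_in_window(ev: IndelEvent, ref: AmpliconRef) -> bool:
    lo, hi = ref.target_window
    if ev.kind == "del":
        return ev.position < hi and ev.position + ev.length > lo
    left, right = insertion_placement_range(ref.sequence, ev.position, ev.bases)
    return right >= lo and left <= hi


def classify_read(
    alignment: AlignmentResult, ref: AmpliconRef, read_id: str = ""
) -> ReadOutcome:
    """Assign a read to no_change / insertion / deletion from its alignment.

    Events outside the target window are ignored.  Reads carrying both
    insertions and deletions in the window count once, as the type with the
    larger total event length (ties go to insertion).  Reads whose aligned
    span does not cover the window are discarded as truncated.
    """
    lo, hi = ref.target_window
    cov_lo, cov_hi = alignment.ref_covered
    if cov_lo > lo or cov_hi < hi:
        return ReadOutcome(read_id, "discarded", reason="truncated")
    in_window = tuple(e for e in alignment.events if _event_in_window(e, ref))
    ins_len = sum(e.length for e in in_window if e.kind == "ins")
    del_len = sum(e.length for e in in_window if e.kind == "del")
    if ins_len == 0 and del_len == 0:
        return ReadOutcome(read_id, "no_change")
    category = "insertion" if ins_len >= del_len else "deletion"
    return ReadOutcome(read_id, category, events=in_window)


def indel_summary(outcomes: Iterable[ReadOutcome]) -> IndelSummary:
    """Tally categories over all retained (non-discarded) reads."""
    counts = {"no_change": 0, "insertion": 0, "deletion": 0}
    for o in outcomes:
        if o.category == "discarded":
            continue
        counts[o.category] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no retained reads to summarize")
    return IndelSummary(
        total_reads=total,
        n_no_change=counts["no_change"],
        n_insertion=counts["insertion"],
        n_deletion=counts["deletion"],
    )


def size_spectrum(
    outcomes: Sequence[ReadOutcome],
) -> tuple[dict[int, float], dict[int, float]]:
    """Per-length insertion and deletion percentages over retained reads.

    Each read contributes once, to the histogram of its assigned category,
    at the total event length of that category within the window.
    """
    retained = [o for o in outcomes if o.category != "discarded"]
    total = len(retained)
    if total == 0:
        return {}, {}
    ins_counts: dict[int, int] = {}
    del_counts: dict[int, int] = {}
    for o in retained:
        if o.category == "insertion":
            n = sum(e.length for e in o.events if e.kind == "ins")
            ins_counts[n] = ins_counts.get(n, 0) + 1
        elif o.category == "deletion":
            n = sum(e.length for e in o.events if e.kind == "del")
            del_counts[n] = del_counts.get(n, 0) + 1
    return (
        {k: 100.0 * v / total for k, v in sorted(ins_counts.items())},
        {k: 100.0 * v / total for k, v in sorted(del_counts.items())},
    )


def insertion_base_composition(
    outcomes: Iterable[ReadOutcome], ref: AmpliconRef
) -> InsertionComposition:
    """Base counts of reads whose single event is a 1-bp insertion that can
    be placed between the A and T of the reference start codon."""
    codon_between = ref.start_codon_offset + 1  # between A and T
    counts = {"A": 0, "T": 0, "G": 0, "C": 0}
    for o in outcomes:
        if o.category != "insertion" or len(o.events) != 1:
            continue
        ev = o.events[0]
        if ev.kind != "ins" or ev.length != 1:
            continue
        left, right = insertion_placement_range(ref.sequence, ev.position, ev.bases)
        if left <= codon_between <= right:
            counts[ev.bases] += 1
    return InsertionComposition(counts)


def kozak_assessment(
    event: IndelEvent | None, ref: AmpliconRef, search: int = 2
) -> KozakCall:
    """Check whether the (possibly edited) locus still carries a start codon.

    With ``event=None`` the unedited reference is assessed.  Otherwise
    ``event`` must be a single-base insertion within the start codon; the
    edited sequence is reconstructed and scanned for an ATG whose A lies
    within ``search`` bases of the original offset.  The base three
    positions upstream of that A decides Kozak favorability (A or G).
    """
    o = ref.start_codon_offset
    if event is None:
        seq = ref.sequence
    else:
        if event.kind != "ins" or event.length != 1:
            raise ValueError("event must be a single-base insertion")
        left, right = insertion_placement_range(
            ref.sequence, event.position, event.bases
        )
        if not (left <= o + 3 and right >= o):
            raise ValueError("insertion is not within the start codon")
        seq = event.apply(ref.sequence)
    candidates = [
        i
        for i in range(max(3, o - search), min(len(seq) - 2, o + search + 1))
        if seq[i : i + 3] == "ATG"
    ]
    if not candidates:
        return KozakCall(cryptic_atg_present=False)
    best = min(candidates, key=lambda i: abs(i - o))
    return KozakCall(
        cryptic_atg_present=True,
        new_atg_offset=best,
        minus3_base=seq[best - 3],
    )


def clear_alignment_cache() -> None:
    _CACHE.clear()
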