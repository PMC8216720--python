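"""Gap-tolerant cut-site calling from in-vitro digestion sequencing.

A Cas9 cleavage event in purified genomic DNA turns one fragment into two,
so sequencing reads pile up with their 5' ends exactly at the cleavage
point: forward reads start at the first base of the right fragment and
reverse reads end at the last base of the left fragment.  The caller builds
strand-specific read-start and coverage profiles, keeps positions where at
least ``min_starts`` reads begin and those starts make up at least
``min_frac`` of the strand's coverage, joins plus/minus positions allowing
a +/- 1 bp stagger (blunt end, 1 bp gap, 1 bp overhang), and scores each
joined site as the combined-strand percentage of covering reads that start
at it.  Sites scoring above ``score_threshold`` are reported.

Coordinates are 0-based half-open internally; TSV reports are 1-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

__all__ = [
    "AlignmentRecord",
    "StartProfile",
    "FilteredStart",
    "CutSiteCandidate",
    "DetectorConfig",
    "read_alignments",
    "strand_start_profiles",
    "filter_start_positions",
    "join_cut_sites",
    "digenome_score",
    "call_candidates",
    "write_candidates_tsv",
    "GAP_GEOMETRY",
]

#: Mapping from joined-site gap value to cleavage geometry label.
GAP_GEOMETRY = {0: "blunt", 1: "gap1", -1: "overhang1"}


@dataclass(frozen=True)
class AlignmentRecord:
    """One mapped read reduced to what the detector needs."""

    contig: str
    start: int  # 0-based leftmost aligned reference position
    length: int  # aligned reference span in bases
    strand: str  # '+' or '-'
    name: str = ""
    is_secondary: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.length <= 0:
            raise ValueError("aligned length must be positive")
        if self.start < 0:
            raise ValueError("start must be non-negative")

    @property
    def end(self) -> int:
        """One past the rightmost aligned reference position."""
        return self.start + self.length

    @property
    def read_start(self) -> int:
        """5'-end position on the read's own strand.

        Leftmost aligned base for a forward read, rightmost for a reverse
        read — the convention that makes a blunt cut satisfy
        ``plus_start == minus_start + 1``.
        """
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class StartProfile:
    """Strand-specific read-start counts and coverage over one region."""

    contig: str
    region_start: int
    s_plus: np.ndarray
    d_plus: np.ndarray
    s_minus: np.ndarray
    d_minus: np.ndarray

    @property
    def region_end(self) -> int:
        return self.region_start + len(self.s_plus)

    def validate(self) -> None:
        for s, d in ((self.s_plus, self.d_plus), (self.s_minus, self.d_minus)):
            if (s < 0).any() or (d < 0).any():
                raise ValueError("negative counts in profile")
            if (s > d).any():
                raise ValueError("read starts exceed coverage")


@dataclass(frozen=True)
class FilteredStart:
    """A read-start position that survived both filters on its strand."""

    contig: str
    position: int  # 0-based
    strand: str
    starts: int
    depth: int

    @property
    def perc(self) -> float:
        """Read starts as a percentage of same-strand coverage."""
        return 100.0 * self.starts / self.depth


@dataclass(frozen=True)
class CutSiteCandidate:
    """A joined plus/minus cut-site call."""

    contig: str
    start: int  # 0-based reported coordinate: min(plus pos, minus pos + 1)
    gap: int  # 0 blunt, +1 one-bp gap, -1 one-bp overhang
    plus: FilteredStart
    minus: FilteredStart

    @property
    def geometry(self) -> str:
        return GAP_GEOMETRY[self.gap]

    @property
    def score(self) -> float:
        return digenome_score(
            self.plus.starts, self.plus.depth, self.minus.starts, self.minus.depth
        )


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable thresholds of the cut-site caller."""

    min_starts: int = 5
    min_frac: float = 0.25
    score_threshold: float = 60.0
    allowed_gaps: tuple[int, ...] = (-1, 0, 1)
    count_secondary_alignments: bool = False

    def __post_init__(self) -> None:
        if self.min_starts < 1:
            raise ValueError("min_starts must be >= 1")
        if not 0 < self.min_frac <= 1:
            raise ValueError("min_frac must be in (0, 1]")
        if not 0 <= self.score_threshold <= 100:
            raise ValueError("score_threshold must be in [0, 100]")
        if any(abs(g) > 1 for g in self.allowed_gaps):
            raise ValueError("gaps beyond +/-1 are not supported")


def read_alignments(path: str | Path) -> list[AlignmentRecord]:
    """Load mapped records from a coordinate-sorted SAM/BAM file.

    Unmapped records are dropped; secondary/supplementary records are kept
    but flagged so the profile builder can exclude them (the default).
    Raises ``ValueError`` if records are not coordinate-sorted.
    """
    records: list[AlignmentRecord] = []
    last: tuple[str, int] | None = None
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for seg in af:
            if seg.is_unmapped or seg.reference_length is None:
                continue
            key = (seg.reference_name, seg.reference_start)
            if last is not None and key[0] == last[0] and key[1] < last[1]:
                raise ValueError("alignments are not coordinate-sorted")
            last = key
            records.append(
                AlignmentRecord(
                    contig=seg.reference_name,
                    start=seg.reference_start,
                    length=seg.reference_length,
                    strand="-" if seg.is_reverse else "+",
                    name=seg.query_name or "",
                    is_secondary=seg.is_secondary or seg.is_supplementary,
                )
            )
    return records


def _check_sorted(alignments: Sequence[AlignmentRecord]) -> None:
    for a, b in zip(alignments, alignments[1:]):
        if a.contig == b.contig and b.start < a.start:
            raise ValueError("alignments are not coordinate-sorted")


def strand_start_profiles(
    alignments: Sequence[AlignmentRecord],
    region: tuple[int, int] | None = None,
    include_secondary: bool = False,
) -> StartProfile:
    """Build strand-specific read-start and coverage arrays.

    ``alignments`` must all lie on one contig and be coordinate-sorted.
    ``region`` is a 0-based half-open interval; when omitted, the tight
    span of the alignments is used.
    """
    usable = [a for a in alignments if include_secondary or not a.is_secondary]
    contigs = {a.contig for a in usable}
    if len(contigs) > 1:
        raise ValueError(f"alignments span multiple contigs: {sorted(contigs)}")
    contig = contigs.pop() if contigs else ""
    _check_sorted(usable)

    if region is None:
        if not usable:
            return StartProfile(contig, 0, *(np.zeros(0, dtype=np.int64),) * 4)
        region = (min(a.start for a in usable), max(a.end for a in usable))
    lo, hi = region
    if hi < lo:
        raise ValueError("region end before region start")
    n = hi - lo
    s_plus = np.zeros(n, dtype=np.int64)
    d_plus = np.zeros(n, dtype=np.int64)
    s_minus = np.zeros(n, dtype=np.int64)
    d_minus = np.zeros(n, dtype=np.int64)

    for a in usable:
        cov_lo, cov_hi = max(a.start, lo), min(a.end, hi)
        if cov_lo < cov_hi:
            if a.strand == "+":
                d_plus[cov_lo - lo : cov_hi - lo] += 1
            else:
                d_minus[cov_lo - lo : cov_hi - lo] += 1
        p = a.read_start
        if lo <= p < hi:
            (s_plus if a.strand == "+" else s_minus)[p - lo] += 1

    return StartProfile(contig, lo, s_plus, d_plus, s_minus, d_minus)


def filter_start_positions(
    profile: StartProfile, cfg: DetectorConfig | None = None
) -> list[FilteredStart]:
    """Keep positions with ``>= min_starts`` read starts making up
    ``>= min_frac`` of that strand's coverage (both boundaries inclusive)."""
    if cfg is None:
        cfg = DetectorConfig()
    profile.validate()
    hits: list[FilteredStart] = []
    for strand, s, d in (
        ("+", profile.s_plus, profile.d_plus),
        ("-", profile.s_minus, profile.d_minus),
    ):
        idx = np.nonzero(s >= cfg.min_starts)[0]
        for i in idx:
            if s[i] >= cfg.min_frac * d[i]:
                hits.append(
                    FilteredStart(
                        contig=profile.contig,
                        position=profile.region_start + int(i),
                        strand=strand,
                        starts=int(s[i]),
                        depth=int(d[i]),
                    )
                )
    return hits


def join_cut_sites(
    plus_hits: Iterable[FilteredStart],
    minus_hits: Iterable[FilteredStart],
    cfg: DetectorConfig | None = None,
) -> list[CutSiteCandidate]:
    """Pair filtered plus/minus positions into cut-site candidates.

    A plus-strand start at ``p`` and minus-strand start at ``m`` join with
    gap ``g = p - m - 1``; ``g`` must be one of ``cfg.allowed_gaps``
    (0 blunt, +1 one-bp gap, -1 one-bp overhang).  The reported start is
    ``min(p, m + 1)``.
    """
    if cfg is None:
        cfg = DetectorConfig()
    by_pos: dict[int, list[FilteredStart]] = {}
    for h in minus_hits:
        by_pos.setdefault(h.position, []).append(h)
    out: list[CutSiteCandidate] = []
    for ph in plus_hits:
        for g in cfg.allowed_gaps:
            m = ph.position - 1 - g
            for mh in by_pos.get(m, ()):
                if mh.contig != ph.contig:
                    raise ValueError("plus and minus hits from different contigs")
                out.append(
                    CutSiteCandidate(
                        contig=ph.contig,
                        start=min(ph.position, mh.position + 1),
                        gap=g,
                        plus=ph,
                        minus=mh,
                    )
                )
    return out


def digenome_score(
    s_plus: int, d_plus: int, s_minus: int, d_minus: int
) -> float:
    """Combined-strand percentage of covering reads that start at the site.

    ``100 * (S+ + S-) / (D+ + D-)``; 100 iff every covering read on both
    strands starts exactly at the site.
    """
    depth = d_plus + d_minus
    if depth <= 0:
        raise ValueError("combined depth must be positive")
    if s_plus > d_plus or s_minus > d_minus:
        raise ValueError("read starts cannot exceed depth")
    return 100.0 * (s_plus + s_minus) / depth


def call_candidates(
    alignments: Sequence[AlignmentRecord],
    cfg: DetectorConfig | None = None,
) -> list[CutSiteCandidate]:
    """Run the full caller: profiles -> filters -> joining -> score cut.

    Only candidates with score strictly above ``cfg.score_threshold`` are
    returned, best score first; ties break on (contig, start, gap).
    """
    if cfg is None:
        cfg = DetectorConfig()
    by_contig: dict[str, list[AlignmentRecord]] = {}
    for a in alignments:
        by_contig.setdefault(a.contig, []).append(a)
    out: list[CutSiteCandidate] = []
    for contig in sorted(by_contig):
        profile = strand_start_profiles(
            by_contig[contig], include_secondary=cfg.count_secondary_alignments
        )
        hits = filter_start_positions(profile, cfg)
        plus = [h for h in hits if h.strand == "+"]
        minus = [h for h in hits if h.strand == "-"]
        for cand in join_cut_sites(plus, minus, cfg):
            if cand.score > cfg.score_threshold:
                out.append(cand)
    out.sort(key=lambda c: (-c.score, c.contig, c.start, c.gap))
    return out


def _fmt(x: float) -> str:
    return f"{round(x, 2):g}"


def write_candidates_tsv(
    candidates: Sequence[CutSiteCandidate], path: str | Path
) -> None:
    """Write candidates as a TSV (1-based Start, percentages to 2 dp)."""
    header = [
        "Chr", "Gap", "Start",
        "Plus", "Depth", "Perc",
        "Minus", "Depth2", "Perc2",
        "Total",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for c in candidates:
            row = [
                c.contig, str(c.gap), str(c.start + 1),
                str(c.plus.starts), str(c.plus.depth), _fmt(c.plus.perc),
                str(c.minus.starts), str(c.minus.depth), _fmt(c.minus.perc),
                _fmt(c.score),
            ]
            fh.write("\t".join(row) + "\n")


def write_run_manifest(
    path: str | Path, cfg: DetectorConfig, n_alignments: int, n_candidates: int
) -> None:
    manifest = {
        "config": {
            "min_starts": cfg.min_starts,
            "min_frac": cfg.min_frac,
            "score_threshold": cfg.score_threshold,
            "allowed_gaps": list(cfg.allowed_gaps),
            "count_secondary_alignments": cfg.count_secondary_alignments,
        },
        "n_alignments": n_alignments,
        "n_candidates": n_candidates,
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
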