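"""Guide-homology classification of candidate cut sites.

Each candidate site is scanned, on both strands, for the best match to the
guide-plus-PAM sequence; matches are scored as position-wise percent
identity over the full guide+PAM length (a single gap is allowed and counts
as one mismatch).  Candidates split into with-homology (identity above
threshold and PAM present) and without-homology tables, with genomic
context labels drawn from an annotation file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .digenome import CutSiteCandidate

__all__ = [
    "GuideSpec",
    "HomologyHit",
    "Feature",
    "ClassifiedCandidates",
    "match_identity",
    "pam_check",
    "scan_window",
    "classify_candidates",
    "annotate_context",
    "load_annotation",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")

#: IUPAC degenerate nucleotide codes.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GuideSpec:
    """A guide RNA: protospacer, degenerate PAM, and the on-target sequence."""

    protospacer: str
    pam_pattern: str = "NGG"
    target_with_pam: str = ""

    def __post_init__(self) -> None:
        if not 19 <= len(self.protospacer) <= 20:
            raise ValueError("protospacer must be 19-20 nt")
        if len(self.pam_pattern) != 3:
            raise ValueError("PAM pattern must be 3 nt")
        if self.target_with_pam and len(self.target_with_pam) != len(
            self.protospacer
        ) + 3:
            raise ValueError("target_with_pam must be protospacer + PAM")

    @property
    def full_length(self) -> int:
        return len(self.protospacer) + 3


@dataclass(frozen=True)
class HomologyHit:
    """Best guide match in a genomic window around a candidate site."""

    sequence: str  # candidate sequence, may contain one '-' gap column
    strand: str
    position: int  # 0-based genomic start of the matched window
    identity: float  # percent, PAM positions included
    pam_ok: bool
    context: str = "unknown"


@dataclass(frozen=True)
class Feature:
    """One annotation interval (0-based half-open)."""

    contig: str
    start: int
    end: int
    kind: str  # 'exon' | 'gene' | 'antisense'
    name: str = ""
    strand: str = "."


@dataclass
class ClassifiedCandidates:
    """Treated candidates split by homology, plus control candidates."""

    with_homology: list[tuple[CutSiteCandidate, HomologyHit]]
    without_homology: list[tuple[CutSiteCandidate, HomologyHit]]
    control: list[CutSiteCandidate]


def match_identity(target_with_pam: str, candidate: str) -> float:
    """Percent position-wise identity over the full target length.

    ``candidate`` may contain at most one ``-`` gap column, which always
    counts as a mismatch.  PAM positions are included in the denominator.
    """
    if len(candidate) != len(target_with_pam):
        raise ValueError("sequences must have equal length after gap placement")
    if candidate.count("-") > 1:
        raise ValueError("at most one gap character is allowed")
    matches = sum(
        1 for a, b in zip(target_with_pam, candidate) if a == b and b != "-"
    )
    return 100.0 * matches / len(target_with_pam)


def pam_check(seq: str, pattern: str = "NGG") -> bool:
    """True iff the last ``len(pattern)`` bases match the degenerate motif."""
    if len(seq) < len(pattern):
        raise ValueError("sequence shorter than the PAM pattern")
    tail = seq.replace("-", "")[-len(pattern) :]
    if len(tail) < len(pattern):
        return False
    return all(b in IUPAC[p] for b, p in zip(tail, pattern))


def _candidates_in_window(window: str, length: int):
    """Yield (subsequence, window_offset) for every ungapped and single-gap
    placement of a ``length``-column candidate within ``window``."""
    for i in range(len(window) - length + 1):
        yield window[i : i + length], i
    # one gap column: genome contributes length-1 bases
    for i in range(len(window) - (length - 1) + 1):
        sub = window[i : i + length - 1]
        for j in range(1, length - 1):  # internal gaps only
            yield sub[:j] + "-" + sub[j:], i


def scan_window(
    genome: Mapping[str, str],
    site: CutSiteCandidate,
    guide: GuideSpec,
    window: int = 25,
) -> HomologyHit:
    """Find the best guide+PAM match around a candidate cut site.

    Both strands over ``site.start +/- window`` are searched across every
    ungapped offset and every internal single-gap placement.  Ties prefer a
    PAM-bearing hit, then the leftmost placement on the plus strand.
    """
    target = guide.target_with_pam or guide.protospacer + guide.pam_pattern
    length = len(target)
    if window < length:
        raise ValueError("window must be at least the guide+PAM length")
    raw = genome[site.contig]
    contig_seq = raw if isinstance(raw, str) else str(raw[:])
    if not 0 <= site.start <= len(contig_seq):
        raise ValueError("site outside genome")
    lo = max(0, site.start - window)
    hi = min(len(contig_seq), site.start + window)
    fwd = contig_seq[lo:hi].upper()

    best_key: tuple[float, int, int, int] | None = None
    best_hit: HomologyHit | None = None
    for strand, seq in (("+", fwd), ("-", reverse_complement(fwd))):
        for cand, off in _candidates_in_window(seq, length):
            ident = match_identity(target, cand)
            ok = pam_check(cand, guide.pam_pattern)
            span = len(cand) - cand.count("-")
            gpos = lo + off if strand == "+" else hi - off - span
            # maximize identity, then PAM presence, then leftmost genomic
            # position, preferring the plus strand on exact ties
            key = (ident, int(ok), -gpos, int(strand == "+"))
            if best_key is None or key > best_key:
                best_key = key
                best_hit = HomologyHit(
                    sequence=cand, strand=strand, position=gpos,
                    identity=ident, pam_ok=ok,
                )
    assert best_hit is not None
    return best_hit


def annotate_context(
    contig: str, start: int, end: int, features: Sequence[Feature] | None
) -> str:
    """Context label for an interval: coding > intron > antisense > intergenic.

    ``exon`` features give 'coding'; a 'gene' overlap without an exon gives
    'intron'; genes flagged antisense give 'antisense'; no overlap at all is
    'intergenic'.  ``None`` annotation yields 'unknown'.
    """
    if features is None:
        return "unknown"
    overlapping = [
        f
        for f in features
        if f.contig == contig and f.start < end and f.end > start
    ]
    kinds = {f.kind for f in overlapping}
    if "exon" in kinds:
        return "coding"
    if "gene" in kinds:
        return "intron"
    if "antisense" in kinds:
        return "antisense"
    return "intergenic"


_ANTISENSE_NAME = re.compile(r"-AS\d*$")


def _feature_kind(raw_type: str, name: str) -> str | None:
    t = raw_type.lower()
    if t in ("exon", "cds"):
        return "exon"
    if "antisense" in t or _ANTISENSE_NAME.search(name or ""):
        return "antisense"
    if t in ("gene", "mrna", "transcript", "lnc_rna", "ncrna"):
        return "gene"
    return None


def load_annotation(path: str | Path) -> list[Feature]:
    """Load features from BED (0-based) or GFF3 (1-based) into intervals.

    BED columns: chrom, start, end, name[, score, strand[, feature_type]];
    the feature type defaults to 'exon'.  GFF3 uses column 3 as the type and
    the Name/ID/gene_name attribute as the name.  Antisense genes are
    recognized by type or a ``-AS`` name suffix.
    """
    path = Path(path)
    features: list[Feature] = []
    if path.suffix.lower() in (".gff", ".gff3", ".gtf"):
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["seqid", "source", "type", "start", "end",
                   "score", "strand", "phase", "attributes"],
            dtype={"seqid": str},
        )
        for row in df.itertuples(index=False):
            name = ""
            for m in re.finditer(r"(?:Name|gene_name|ID)=([^;]+)", str(row.attributes)):
                name = m.group(1)
                break
            kind = _feature_kind(str(row.type), name)
            if kind is None:
                continue
            features.append(
                Feature(str(row.seqid), int(row.start) - 1, int(row.end),
                        kind, name, str(row.strand))
            )
    else:
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
        for row in df.itertuples(index=False):
            vals = list(row)
            contig, start, end = vals[0], int(vals[1]), int(vals[2])
            name = vals[3] if len(vals) > 3 and pd.notna(vals[3]) else ""
            strand = vals[5] if len(vals) > 5 and pd.notna(vals[5]) else "."
            raw_type = vals[6] if len(vals) > 6 and pd.notna(vals[6]) else "exon"
            kind = _feature_kind(raw_type, name)
            if kind is None:
                raise ValueError(f"malformed annotation record: {vals!r}")
            features.append(Feature(contig, start, end, kind, name, strand))
    return features


def classify_candidates(
    treated: Sequence[CutSiteCandidate],
    control: Sequence[CutSiteCandidate],
    guide: GuideSpec,
    genome: Mapping[str, str],
    annotation: Sequence[Feature] | None = None,
    identity_threshold: float = 70.0,
    window: int = 25,
) -> ClassifiedCandidates:
    """Split treated candidates by guide homology; report control separately.

    A candidate lands in the with-homology table iff its best window hit has
    ``identity >= identity_threshold`` and a PAM.  With-homology rows carry
    a genomic context label (``unknown`` when no annotation is given).
    """
    with_h: list[tuple[CutSiteCandidate, HomologyHit]] = []
    without_h: list[tuple[CutSiteCandidate, HomologyHit]] = []
    for cand in treated:
        hit = scan_window(genome, cand, guide, window)
        if hit.identity >= identity_threshold and hit.pam_ok:
            span = len(hit.sequence.replace("-", ""))
            hit = replace(
                hit,
                context=annotate_context(
                    cand.contig, hit.position, hit.position + span, annotation
                ),
            )
            with_h.append((cand, hit))
        else:
            without_h.append((cand, hit))
    return ClassifiedCandidates(
        with_homology=with_h, without_homology=without_h, control=list(control)
    )


def write_classified_tsv(
    result: ClassifiedCandidates, outdir: str | Path
) -> dict[str, Path]:
    """Write the three candidate tables; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def cand_row(c: CutSiteCandidate) -> dict:
        return {
            "Chr": c.contig, "Gap": c.gap, "Start": c.start + 1,
            "Plus": c.plus.starts, "Depth": c.plus.depth,
            "Perc": round(c.plus.perc, 2),
            "Minus": c.minus.starts, "Depth2": c.minus.depth,
            "Perc2": round(c.minus.perc, 2),
            "Total": round(c.score, 2),
        }

    rows = []
    for cand, hit in result.with_homology:
        row = cand_row(cand)
        row.update(
            {
                "Gene": hit.context,
                "Sequence with PAM": hit.sequence,
                "Identity": round(hit.identity, 1),
            }
        )
        rows.append(row)
    paths["with_homology"] = outdir / "with_homology.tsv"
    pd.DataFrame(rows).to_csv(paths["with_homology"], sep="\t", index=False)

    rows = []
    for cand, hit in result.without_homology:
        row = cand_row(cand)
        row.update({"Best sequence": hit.sequence,
                    "Identity": round(hit.identity, 1)})
        rows.append(row)
    paths["without_homology"] = outdir / "without_homology.tsv"
    pd.DataFrame(rows).to_csv(paths["without_homology"], sep="\t", index=False)

    paths["control"] = outdir / "control.tsv"
    pd.DataFrame([cand_row(c) for c in result.control]).to_csv(
        paths["control"], sep="\t", index=False
    )
    return paths
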