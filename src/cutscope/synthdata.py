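"""Synthetic inputs with known truth for every downstream stage.

Three generators: a toy genome, whole-genome digestion read sets whose
fragment ends pile up at planted cleavage positions over random background
fragmentation, and amplicon read sets carrying a configurable
insertion/deletion spectrum at a start codon.  All randomness flows from
explicit integer seeds and outputs are byte-identical across runs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .digenome import AlignmentRecord

__all__ = [
    "SimGenome",
    "TrueCutSite",
    "IndelEvent",
    "AmpliconSpec",
    "SimRead",
    "simulate_genome",
    "simulate_digenome_reads",
    "simulate_amplicon_reads",
    "plant_sequence",
    "demo_amplicon",
    "build_amplicon_with_sites",
    "write_fasta",
    "write_sam",
    "write_fastq",
    "write_truth_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
GEOMETRIES = ("blunt", "gap1", "overhang1")


@dataclass(frozen=True)
class SimGenome:
    """A toy genome: named ACGT contigs plus the seed that made them."""

    contigs: dict[str, str]
    seed: int

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name} is empty")
            if set(seq) - set("ACGT"):
                raise ValueError(f"contig {name} contains non-ACGT characters")


@dataclass(frozen=True)
class TrueCutSite:
    """A planted cleavage: blunt-cut point between two bases of a contig."""

    contig: str
    position: int  # 0-based between-base coordinate
    geometry: str = "blunt"  # blunt | gap1 | overhang1
    efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError("efficiency must be in [0, 1]")


@dataclass(frozen=True)
class IndelEvent:
    """One editing outcome applied to an amplicon reference.

    ``position`` is a 0-based reference coordinate: for insertions, the
    index before which ``bases`` are inserted; for deletions, the first
    deleted base.
    """

    kind: str  # 'ins' | 'del'
    position: int
    length: int
    bases: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("ins", "del"):
            raise ValueError("kind must be 'ins' or 'del'")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.kind == "ins" and len(self.bases) != self.length:
            raise ValueError("inserted bases must match length")
        if self.kind == "del" and self.bases:
            raise ValueError("deletions carry no bases")

    def apply(self, reference: str) -> str:
        if self.kind == "ins":
            if not 0 <= self.position <= len(reference):
                raise ValueError("insertion position outside reference")
            return reference[: self.position] + self.bases + reference[self.position :]
        if self.position < 0 or self.position + self.length > len(reference):
            raise ValueError("deletion outside reference")
        return reference[: self.position] + reference[self.position + self.length :]


@dataclass(frozen=True)
class AmpliconSpec:
    """Recipe for an amplicon read set with a known indel spectrum."""

    reference: str
    start_codon_offset: int
    indel_spectrum: dict[IndelEvent, float]
    n_reads: int
    quality_mean: float = 35.0
    quality_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.start_codon_offset + 3 > len(self.reference):
            raise ValueError("start codon extends past the reference")
        total = sum(self.indel_spectrum.values())
        if total > 1.0 + 1e-9:
            raise ValueError("spectrum probabilities sum to more than 1")
        if any(p < 0 for p in self.indel_spectrum.values()):
            raise ValueError("negative event probability")
        if self.n_reads < 0:
            raise ValueError("n_reads must be non-negative")
        for ev in self.indel_spectrum:
            ev.apply(self.reference)  # validates positions


@dataclass(frozen=True)
class SimRead:
    """One simulated FASTQ record plus its truth event (None = unedited)."""

    name: str
    sequence: str
    qualities: tuple[int, ...]
    event: IndelEvent | None


def simulate_genome(
    n_contigs: int, length: int, gc: float = 0.5, seed: int = 0
) -> SimGenome:
    """Random ACGT contigs with the requested GC fraction."""
    if length < 1:
        raise ValueError("contig length must be positive")
    if n_contigs < 1:
        raise ValueError("need at least one contig")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at, gccomp = (1.0 - gc) / 2.0, gc / 2.0
    probs = [at, gccomp, gccomp, at]  # A C G T
    contigs = {}
    for i in range(n_contigs):
        draw = rng.choice(_BASES, size=length, p=probs)
        contigs[f"chr{i + 1}"] = draw.tobytes().decode()
    return SimGenome(contigs=contigs, seed=seed)


def plant_sequence(genome: SimGenome, contig: str, position: int, sequence: str) -> SimGenome:
    """Return a copy of ``genome`` with ``sequence`` written in at ``position``."""
    seq = genome.contigs[contig]
    if not 0 <= position <= len(seq) - len(sequence):
        raise ValueError("planted sequence does not fit in contig")
    new = seq[:position] + sequence + seq[position + len(sequence) :]
    contigs = dict(genome.contigs)
    contigs[contig] = new
    return replace(genome, contigs=contigs)


def _split_piece(
    piece: tuple[int, int], cut: TrueCutSite
) -> list[tuple[int, int]]:
    """Split a fragment piece [s, e) at a cut it spans, per geometry."""
    s, e = piece
    c = cut.position
    if cut.geometry == "blunt":
        left, right = (s, c), (c, e)
    elif cut.geometry == "gap1":  # one base lost between the two pieces
        left, right = (s, c), (min(c + 1, e), e)
    else:  # overhang1: one base covered by both pieces
        left, right = (s, min(c + 1, e)), (c, e)
    return [p for p in (left, right) if p[1] > p[0]]


def simulate_digenome_reads(
    genome: SimGenome,
    cuts: Sequence[TrueCutSite],
    mean_depth: float = 30.0,
    read_len: int = 100,
    frag_mean: float = 350.0,
    frag_sigma: float = 0.25,
    seed: int = 0,
) -> tuple[list[AlignmentRecord], list[dict]]:
    """Shear the genome into random fragments, split those spanning a cut,
    and emit paired end reads as coordinate-sorted alignment records.

    Background fragmentation draws lognormal fragment lengths at uniform
    positions; each final piece yields one forward read at its left edge and
    one reverse read ending at its right edge, so cleavage sites show up as
    strand-specific read-start pileups with the planted geometry.  Returns
    the sorted records plus a truth sidecar (one dict per read with its
    source fragment/piece interval).
    """
    for cut in cuts:
        if cut.contig not in genome.contigs:
            raise ValueError(f"cut on unknown contig {cut.contig}")
        if not 0 < cut.position < len(genome.contigs[cut.contig]):
            raise ValueError("cut position outside contig")
    rng = np.random.default_rng(seed)
    records: list[AlignmentRecord] = []
    truth: list[dict] = []

    for contig in sorted(genome.contigs):
        clen = len(genome.contigs[contig])
        if read_len >= clen:
            raise ValueError("read length must be shorter than the contig")
        contig_cuts = sorted(
            (c for c in cuts if c.contig == contig), key=lambda c: c.position
        )
        n_frags = max(1, round(mean_depth * clen / (2.0 * read_len)))
        starts = rng.integers(0, clen, size=n_frags)
        lengths = rng.lognormal(np.log(frag_mean), frag_sigma, size=n_frags)
        cut_rolls = rng.random(size=(n_frags, max(1, len(contig_cuts))))

        for i in range(n_frags):
            s = int(starts[i])
            e = min(clen, s + max(1, int(round(lengths[i]))))
            if e <= s:
                continue
            pieces = [(s, e)]
            for j, cut in enumerate(contig_cuts):
                if cut_rolls[i, j] >= cut.efficiency:
                    continue
                nxt: list[tuple[int, int]] = []
                for piece in pieces:
                    if piece[0] < cut.position < piece[1]:
                        nxt.extend(_split_piece(piece, cut))
                    else:
                        nxt.append(piece)
                pieces = nxt
            for k, (ps, pe) in enumerate(pieces):
                plen = pe - ps
                fwd_len = min(read_len, plen)
                name = f"frag{contig}_{i}_{k}"
                fwd = AlignmentRecord(contig, ps, fwd_len, "+", name=name + "/1")
                rev = AlignmentRecord(
                    contig, max(ps, pe - read_len), min(read_len, plen), "-",
                    name=name + "/2",
                )
                for rec in (fwd, rev):
                    records.append(rec)
                    truth.append(
                        {
                            "read": rec.name,
                            "contig": contig,
                            "read_start": rec.start,
                            "read_end": rec.end,
                            "strand": rec.strand,
                            "fragment_start": s,
                            "fragment_end": e,
                            "piece_start": ps,
                            "piece_end": pe,
                        }
                    )

    order = sorted(range(len(records)), key=lambda i: (records[i].contig, records[i].start))
    records = [records[i] for i in order]
    truth = [truth[i] for i in order]
    return records, truth


def simulate_amplicon_reads(spec: AmpliconSpec) -> list[SimRead]:
    """Draw ``n_reads`` amplicon reads from the configured indel spectrum.

    Each read is the reference with at most one event applied; the residual
    probability mass yields unedited reads.  Per-base qualities are normal
    draws clipped to [2, 41].
    """
    rng = np.random.default_rng(spec.seed)
    events = list(spec.indel_spectrum)
    probs = [spec.indel_spectrum[e] for e in events]
    p_none = max(0.0, 1.0 - sum(probs))
    choices = rng.choice(len(events) + 1, size=spec.n_reads, p=probs + [p_none])

    reads: list[SimRead] = []
    for i in range(spec.n_reads):
        idx = int(choices[i])
        event = events[idx] if idx < len(events) else None
        seq = event.apply(spec.reference) if event else spec.reference
        quals = np.clip(
            np.rint(rng.normal(spec.quality_mean, spec.quality_sd, size=len(seq))),
            2, 41,
        ).astype(int)
        reads.append(
            SimRead(
                name=f"read{i}",
                sequence=seq,
                qualities=tuple(int(q) for q in quals),
                event=event,
            )
        )
    return reads


# ---------------------------------------------------------------------------
# canned references

# Amplicon core mirroring a start-codon target locus: the protospacer
# CCATCCACAGACGCCATGC sits immediately 5' of an AGG PAM, with the ATG at the
# center of the amplicon and a favorable G at the -3 position.
_DEMO_CORE = "CCCATCCACAGACGCCATGCAGG"


def demo_amplicon(length: int = 155, seed: int = 99) -> tuple[str, int]:
    """A deterministic amplicon reference with a centered start codon.

    Returns ``(sequence, start_codon_offset)``.  Flanks are random but free
    of additional ATG triplets near the core and of CATG motifs, so the
    start-codon CATG is the only restriction site.
    """
    core = _DEMO_CORE
    core_atg = core.index("ATG", 10)
    flank_left = (length - len(core)) // 2
    flank_right = length - len(core) - flank_left
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        left = "".join(rng.choice(list("ACGT"), size=flank_left))
        right = "".join(rng.choice(list("ACGT"), size=flank_right))
        seq = left + core + right
        offset = flank_left + core_atg
        if seq.count("CATG") == 1:
            return seq, offset
    raise RuntimeError("failed to build a clean amplicon")


def build_amplicon_with_sites(
    fragment_lengths: Sequence[int], motif: str = "CATG", cut_after: int = 1,
    seed: int = 0,
) -> str:
    """Build a sequence whose only motif occurrences produce the requested
    digest fragments (used to prototype gel-band predictions)."""
    total = sum(fragment_lengths)
    cuts = np.cumsum(fragment_lengths[:-1])
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        seq = list("".join(rng.choice(list("ACGT"), size=total)))
        for c in cuts:
            seq[c - cut_after : c - cut_after + len(motif)] = motif
        joined = "".join(seq)
        occ = [i for i in range(len(joined)) if joined.startswith(motif, i)]
        if occ == [int(c) - cut_after for c in cuts]:
            return joined
    raise RuntimeError("failed to place motifs without extra occurrences")


# ---------------------------------------------------------------------------
# writers

def write_fasta(genome: SimGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome.contigs):
            fh.write(f">{name}\n")
            seq = genome.contigs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_sam(
    records: Sequence[AlignmentRecord], genome: SimGenome, path: str | Path
) -> None:
    """Write records as a coordinate-sorted SAM file with header."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": name, "LN": len(genome.contigs[name])}
            for name in sorted(genome.contigs)
        ],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec.name or "read"
            seg.reference_name = rec.contig
            seg.reference_start = rec.start
            seg.mapping_quality = 60
            seg.cigartuples = [(0, rec.length)]  # M
            seg.flag = 16 if rec.strand == "-" else 0
            if rec.is_secondary:
                seg.flag |= 256
            seq = genome.contigs[rec.contig][rec.start : rec.end]
            seg.query_sequence = seq
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            out.write(seg)


def write_fastq(reads: Iterable[SimRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{qual}\n")


def write_truth_tsv(rows: Iterable[dict], path: str | Path) -> None:
    rows = list(rows)
    if not rows:
        Path(path).write_text("")
        return
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]), delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)


def amplicon_truth_rows(reads: Iterable[SimRead]) -> list[dict]:
    """Truth sidecar rows for an amplicon read set."""
    rows = []
    for r in reads:
        ev = r.event
        rows.append(
            {
                "read": r.name,
                "kind": ev.kind if ev else "none",
                "position": ev.position if ev else "",
                "length": ev.length if ev else "",
                "bases": ev.bases if ev else "",
            }
        )
    return rows
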