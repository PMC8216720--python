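"""End-to-end orchestration: discovery + classification, and amplicon
quantification + normalization, with manifests and TSV report writers.

All machine-readable output goes to files under the run's output directory;
log lines go to stderr.  Counts are reconciled across stages and recorded
in a JSON manifest, so a run that silently loses reads fails loudly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import pyfaidx

from . import __version__
from .amplicon import (
    AmpliconRef,
    align_to_amplicon,
    classify_read,
    filter_reads_by_median_quality,
    indel_summary,
    insertion_base_composition,
    read_fastq,
    size_spectrum,
)
from .digenome import (
    DetectorConfig,
    call_candidates,
    read_alignments,
    write_candidates_tsv,
)
from .offtarget import (
    GuideSpec,
    classify_candidates,
    load_annotation,
    write_classified_tsv,
)
from .quantify import CellModel, normalized_indel_rate, summarize_mean_sd

logger = logging.getLogger("cutscope")

__all__ = [
    "DigenomeRunConfig",
    "AmpliconRunConfig",
    "run_digenome_pipeline",
    "run_amplicon_pipeline",
]


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, manifest: dict) -> Path:
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _load_genome(path: str | Path) -> Mapping[str, str]:
    fasta = pyfaidx.Fasta(str(path))
    return {name: str(fasta[name][:]) for name in fasta.keys()}


@dataclass
class DigenomeRunConfig:
    treated_sam: str
    outdir: str
    control_sam: str | None = None
    genome_fasta: str | None = None
    annotation: str | None = None
    guide: GuideSpec | None = None
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    identity_threshold: float = 70.0
    scan_window: int = 25
    seed: int = 0


def run_digenome_pipeline(cfg: DigenomeRunConfig) -> dict:
    """Call cut-site candidates, classify by guide homology, write tables.

    Without a genome + guide the homology stage is skipped with a warning
    and only the raw candidate table is written.  Returns the manifest.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.monotonic()

    treated_alignments = read_alignments(cfg.treated_sam)
    if not treated_alignments:
        raise ValueError("no alignments in treated input")
    treated = call_candidates(treated_alignments, cfg.detector)
    logger.info("[digenome] treated: %d alignments -> %d candidates",
                len(treated_alignments), len(treated))

    control = []
    n_control_alignments = 0
    if cfg.control_sam:
        control_alignments = read_alignments(cfg.control_sam)
        n_control_alignments = len(control_alignments)
        control = call_candidates(control_alignments, cfg.detector)
        logger.info("[digenome] control: %d alignments -> %d candidates",
                    n_control_alignments, len(control))

    write_candidates_tsv(treated, outdir / "candidates.tsv")
    tables = {"candidates": str(outdir / "candidates.tsv")}

    n_with = n_without = None
    if cfg.genome_fasta and cfg.guide:
        genome = _load_genome(cfg.genome_fasta)
        annotation = load_annotation(cfg.annotation) if cfg.annotation else None
        result = classify_candidates(
            treated, control, cfg.guide, genome, annotation,
            cfg.identity_threshold, cfg.scan_window,
        )
        paths = write_classified_tsv(result, outdir)
        tables.update({k: str(v) for k, v in paths.items()})
        n_with = len(result.with_homology)
        n_without = len(result.without_homology)
        if n_with + n_without != len(treated):
            raise AssertionError("classification does not partition candidates")
    else:
        logger.warning("[offtarget] genome or guide missing; homology stage skipped")

    manifest = {
        "tool_version": __version__,
        "seed": cfg.seed,
        "inputs": {
            "treated_sam": {"path": cfg.treated_sam,
                            "sha256": _checksum(cfg.treated_sam)},
            "control_sam": (
                {"path": cfg.control_sam, "sha256": _checksum(cfg.control_sam)}
                if cfg.control_sam else None
            ),
        },
        "config": {
            "min_starts": cfg.detector.min_starts,
            "min_frac": cfg.detector.min_frac,
            "score_threshold": cfg.detector.score_threshold,
            "allowed_gaps": list(cfg.detector.allowed_gaps),
            "identity_threshold": cfg.identity_threshold,
            "scan_window": cfg.scan_window,
        },
        "counts": {
            "treated_alignments": len(treated_alignments),
            "control_alignments": n_control_alignments,
            "treated_candidates": len(treated),
            "control_candidates": len(control),
            "with_homology": n_with,
            "without_homology": n_without,
        },
        "tables": tables,
        "wall_clock_s": round(time.monotonic() - t0, 3),
    }
    _write_manifest(outdir, manifest)
    return manifest


@dataclass
class AmpliconRunConfig:
    samples: list[tuple[str, str]]  # (sample name, fastq path)
    reference: str  # amplicon sequence
    start_codon_offset: int
    outdir: str
    window: int = 10
    quality_cutoff: float = 5.0
    gdna_ng: dict[str, float] | None = None  # sample -> gDNA mass
    cell_model: CellModel = field(default_factory=CellModel)
    seed: int = 0


def _analyze_sample(
    name: str, fastq: str, ref: AmpliconRef, quality_cutoff: float
) -> dict:
    reads = list(read_fastq(fastq))
    retained, low_quality = filter_reads_by_median_quality(reads, quality_cutoff)
    outcomes = [
        classify_read(align_to_amplicon(r.sequence, ref), ref, r.name)
        for r in retained
    ]
    truncated = sum(1 for o in outcomes if o.category == "discarded")
    classified = [o for o in outcomes if o.category != "discarded"]
    if not classified:
        reasons = {"low_median_quality": len(low_quality), "truncated": truncated}
        raise ValueError(f"all reads discarded for sample {name}: {reasons}")
    summary = indel_summary(classified)
    ins_hist, del_hist = size_spectrum(classified)
    composition = insertion_base_composition(classified, ref)
    if len(reads) != len(low_quality) + truncated + summary.total_reads:
        raise AssertionError("read counts do not reconcile")
    return {
        "name": name,
        "n_input": len(reads),
        "n_low_quality": len(low_quality),
        "n_truncated": truncated,
        "summary": summary,
        "ins_hist": ins_hist,
        "del_hist": del_hist,
        "composition": composition,
    }


def run_amplicon_pipeline(cfg: AmpliconRunConfig) -> dict:
    """Quantify editing outcomes for each sample and write summary tables.

    Writes a per-sample category table (with a cross-sample mean +/- SD row
    when more than one sample is given), an inserted-base composition table,
    indel-size histograms, optionally a gDNA-normalized rate table, and a
    manifest with reconciled counts.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.monotonic()
    if not cfg.samples:
        raise ValueError("no samples given")
    ref = AmpliconRef(cfg.reference, cfg.start_codon_offset, cfg.window)

    results = [
        _analyze_sample(name, fastq, ref, cfg.quality_cutoff)
        for name, fastq in cfg.samples
    ]
    for r in results:
        logger.info(
            "[amplicon] %s: %d reads, %d low-quality, %d truncated, indel %.1f%%",
            r["name"], r["n_input"], r["n_low_quality"], r["n_truncated"],
            r["summary"].pct_indel,
        )

    # category table (per-sample rows + mean +/- SD of the ratios)
    rows = []
    for r in results:
        s = r["summary"]
        rows.append(
            {
                "Sample": r["name"], "Total read": s.total_reads,
                "No change": s.n_no_change, "Insertion": s.n_insertion,
                "Deletion": s.n_deletion, "Indel": s.n_indel,
                "No change %": round(s.pct_no_change, 1),
                "Insertion %": round(s.pct_insertion, 1),
                "Deletion %": round(s.pct_deletion, 1),
                "Indel %": round(s.pct_indel, 1),
            }
        )
    if len(results) > 1:
        mean_row = {"Sample": "Average of ratio"}
        for col, attr in (
            ("No change %", "pct_no_change"), ("Insertion %", "pct_insertion"),
            ("Deletion %", "pct_deletion"), ("Indel %", "pct_indel"),
        ):
            mean, sd = summarize_mean_sd(
                [getattr(r["summary"], attr) for r in results]
            )
            mean_row[col] = f"{mean:.1f} +/- {sd:.1f}"
        rows.append(mean_row)
    pd.DataFrame(rows).to_csv(outdir / "indel_summary.tsv", sep="\t", index=False)

    comp_rows = []
    for r in results:
        comp = r["composition"]
        row = {"Sample": r["name"], "Total single insertions": comp.total}
        for base in "ATGC":
            row[base] = comp.counts[base]
            row[f"{base} %"] = (
                round(comp.percentage(base), 1) if comp.total else ""
            )
        comp_rows.append(row)
    pd.DataFrame(comp_rows).to_csv(
        outdir / "insertion_composition.tsv", sep="\t", index=False
    )

    hist_rows = []
    for r in results:
        for kind, hist in (("insertion", r["ins_hist"]), ("deletion", r["del_hist"])):
            for length, pct in hist.items():
                hist_rows.append(
                    {"Sample": r["name"], "Type": kind,
                     "Length": length, "Percent": round(pct, 4)}
                )
    pd.DataFrame(
        hist_rows, columns=["Sample", "Type", "Length", "Percent"]
    ).to_csv(outdir / "size_spectrum.tsv", sep="\t", index=False)

    if cfg.gdna_ng:
        norm_rows = []
        for r in results:
            mass = cfg.gdna_ng.get(r["name"])
            if mass is None:
                continue
            raw = r["summary"].pct_indel
            if raw == 0.0:
                norm_rows.append(
                    {"Sample": r["name"], "gDNA (ng)": mass,
                     "Cells from gDNA": 0 if mass == 0 else
                     normalized_indel_rate(0.0, mass, cfg.cell_model).inferred_cells,
                     "Intact indel rate (%)": 0.0, "Normalized indel rate (%)": 0.0}
                )
                continue
            nr = normalized_indel_rate(raw, mass, cfg.cell_model)
            norm_rows.append(
                {
                    "Sample": r["name"], "gDNA (ng)": mass,
                    "Cells from gDNA": nr.inferred_cells,
                    "Intact indel rate (%)": round(raw, 1),
                    "Normalized indel rate (%)": round(nr.normalized_rate, 1),
                }
            )
        pd.DataFrame(norm_rows).to_csv(
            outdir / "normalized_rates.tsv", sep="\t", index=False
        )

    manifest = {
        "tool_version": __version__,
        "seed": cfg.seed,
        "inputs": {
            name: {"path": fastq, "sha256": _checksum(fastq)}
            for name, fastq in cfg.samples
        },
        "config": {
            "start_codon_offset": cfg.start_codon_offset,
            "window": cfg.window,
            "quality_cutoff": cfg.quality_cutoff,
        },
        "counts": {
            r["name"]: {
                "input_reads": r["n_input"],
                "low_quality": r["n_low_quality"],
                "truncated": r["n_truncated"],
                "retained": r["summary"].total_reads,
            }
            for r in results
        },
        "wall_clock_s": round(time.monotonic() - t0, 3),
    }
    _write_manifest(outdir, manifest)
    return manifest
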