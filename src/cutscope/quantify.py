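"""Cell-number normalization arithmetic and in-silico restriction digestion.

Two unrelated but small pieces of bookkeeping live here:

* converting a purified genomic-DNA mass into an inferred cell count and
  using it to rescale an observed editing rate for contaminating cells, and
* predicting restriction-digest fragment sizes so that loss of a cut site
  (an indel across the recognition motif) shows up as a merged gel band.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

__all__ = [
    "CellModel",
    "NormalizedRate",
    "DigestResult",
    "BandPrediction",
    "cells_from_gdna",
    "normalized_indel_rate",
    "summarize_mean_sd",
    "digest_fragments",
    "indel_band_prediction",
]


@dataclass(frozen=True)
class CellModel:
    """Constants for inferring cell numbers from genomic-DNA mass.

    The default per-cell gDNA mass (5.988 pg) is the value consistent with
    rounding a diploid mouse genome of 5.46e9 bp at 660 g/mol per base pair;
    :meth:`formula_mass_pg` gives the un-rounded product of the constants.
    """

    genome_bp_2n: float = 5.46e9
    bp_molar_mass: float = 660.0  # g/mol per base pair
    avogadro: float = 6.022e23
    per_cell_gdna_pg: float = 5.988
    endothelial_density: float = 2300.0  # cells / mm^2
    endothelial_area_mm2: float = math.pi * 1.0**2

    def __post_init__(self) -> None:
        for name in (
            "genome_bp_2n",
            "bp_molar_mass",
            "avogadro",
            "per_cell_gdna_pg",
            "endothelial_density",
            "endothelial_area_mm2",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def formula_mass_pg(self) -> float:
        """Per-cell gDNA mass in pg derived from the physical constants."""
        grams = self.genome_bp_2n * self.bp_molar_mass / self.avogadro
        return grams * 1e12

    @property
    def expected_cells(self) -> float:
        """Expected cell population of the sampled area (density x area)."""
        return self.endothelial_density * self.endothelial_area_mm2


@dataclass(frozen=True)
class NormalizedRate:
    """An editing rate rescaled by inferred over expected cell number."""

    raw_indel_rate: float  # percent
    gdna_ng: float
    inferred_cells: int
    expected_cells: float
    normalized_rate: float  # percent; may exceed 100


def cells_from_gdna(mass_ng: float, model: CellModel | None = None) -> int:
    """Infer the number of cells contributing ``mass_ng`` of genomic DNA.

    Parameters
    ----------
    mass_ng:
        Purified gDNA mass in nanograms.
    model:
        Constants to use; defaults to :class:`CellModel`.

    Returns
    -------
    int
        ``mass_ng / per_cell_mass_ng`` rounded to the nearest integer.
    """
    if model is None:
        model = CellModel()
    if mass_ng < 0:
        raise ValueError("gDNA mass must be non-negative")
    per_cell_ng = model.per_cell_gdna_pg / 1000.0
    return round(mass_ng / per_cell_ng)


def normalized_indel_rate(
    raw_rate: float, mass_ng: float, model: CellModel | None = None
) -> NormalizedRate:
    """Rescale a raw indel percentage by inferred / expected cell numbers.

    ``raw_rate`` is assumed to be measured over all cells whose gDNA was
    sequenced; when contaminating cells inflate the gDNA yield the edited
    population is under-represented, so the rate is multiplied by the ratio
    of inferred cells to the expected target-cell population.  The result
    can legitimately exceed 100%.
    """
    if model is None:
        model = CellModel()
    if not 0.0 <= raw_rate <= 100.0:
        raise ValueError("raw rate must be a percentage in [0, 100]")
    if mass_ng <= 0:
        raise ValueError("gDNA mass must be positive")
    expected = model.expected_cells
    if expected <= 0:
        raise ValueError("expected cell population must be positive")
    inferred = cells_from_gdna(mass_ng, model)
    return NormalizedRate(
        raw_indel_rate=raw_rate,
        gdna_ng=mass_ng,
        inferred_cells=inferred,
        expected_cells=expected,
        normalized_rate=raw_rate * inferred / expected,
    )


def summarize_mean_sd(values: list[float] | tuple[float, ...]) -> tuple[float, float]:
    """Mean and sample standard deviation (n-1 denominator) of ``values``."""
    if len(values) < 2:
        raise ValueError("need at least two values for mean +/- SD")
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


@dataclass(frozen=True)
class DigestResult:
    """Fragments produced by cutting a sequence at every motif occurrence."""

    motif: str
    cut_after: int  # bases of the motif left of the cut (C^ATG -> 1)
    cut_positions: tuple[int, ...]  # 0-based between-base coordinates
    fragments: tuple[int, ...]  # 5'->3' fragment lengths
    sequence_length: int


@dataclass(frozen=True)
class BandPrediction:
    """Gel bands expected from digesting an edited amplicon."""

    bands: tuple[int, ...]  # observed fragment lengths of the edited digest
    destroyed_cut_positions: tuple[int, ...]  # reference cuts no longer made
    merged_ref_bands: tuple[int, ...]  # reference-scale sizes of merged runs


def digest_fragments(
    sequence: str, motif: str = "CATG", cut_after: int = 1
) -> DigestResult:
    """Cut ``sequence`` at every occurrence of ``motif``.

    The cut is placed ``cut_after`` bases into the motif, so the default
    (CATG, 1) models CviAII/Hin1II cutting C^ATG.  Overlapping motif
    occurrences are all honored.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    if set(sequence) - set("ACGT"):
        raise ValueError("sequence must be uppercase ACGT")
    if not 0 <= cut_after <= len(motif):
        raise ValueError("cut_after must lie within the motif")
    cuts = sorted(
        m.start() + cut_after
        for m in re.finditer(f"(?={re.escape(motif)})", sequence)
    )
    # A cut at position 0 or len(sequence) produces a zero-length fragment;
    # drop those boundary cuts rather than reporting empty fragments.
    cuts = [c for c in cuts if 0 < c < len(sequence)]
    bounds = [0] + cuts + [len(sequence)]
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return DigestResult(
        motif=motif,
        cut_after=cut_after,
        cut_positions=tuple(cuts),
        fragments=fragments,
        sequence_length=len(sequence),
    )


def indel_band_prediction(
    ref_digest: DigestResult, edited_sequence: str
) -> BandPrediction:
    """Predict gel bands after digesting an edited copy of the amplicon.

    Fragments of the edited digest are matched greedily against runs of
    consecutive reference fragments (tolerating the overall length change
    introduced by the edit).  A run of two or more reference fragments
    absorbed by one edited fragment means the intervening reference cut
    site(s) were destroyed; the run's reference-scale size is reported as a
    merged band.
    """
    edited = digest_fragments(
        edited_sequence, ref_digest.motif, ref_digest.cut_after
    )
    ref_frags = list(ref_digest.fragments)
    ref_cuts = list(ref_digest.cut_positions)
    tol = abs(len(edited_sequence) - ref_digest.sequence_length)

    destroyed: list[int] = []
    merged: list[int] = []
    i = 0  # index into reference fragments
    for band in edited.fragments:
        if i >= len(ref_frags):
            break
        acc = ref_frags[i]
        group = 1
        while i + group < len(ref_frags) and acc + ref_frags[i + group] <= band + tol:
            acc += ref_frags[i + group]
            group += 1
        if group > 1:
            merged.append(acc)
            # cuts internal to the merged run (between fragment i and i+group)
            destroyed.extend(ref_cuts[i : i + group - 1])
        i += group
    return BandPrediction(
        bands=edited.fragments,
        destroyed_cut_positions=tuple(destroyed),
        merged_ref_bands=tuple(merged),
    )
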