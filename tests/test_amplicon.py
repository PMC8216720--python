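import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cutscope.amplicon import (
    AlignmentResult,
    AmpliconRef,
    FastqRead,
    IndelSummary,
    InsertionComposition,
    align_to_amplicon,
    classify_read,
    filter_reads_by_median_quality,
    indel_summary,
    insertion_base_composition,
    insertion_placement_range,
    kozak_assessment,
    read_fastq,
    size_spectrum,
)
from cutscope.synthdata import (
    AmpliconSpec,
    IndelEvent,
    demo_amplicon,
    simulate_amplicon_reads,
    write_fastq,
)


def affine_score_oracle(a, b, match=1.0, mismatch=-2.0, open_=-6.0, ext=-1.0):
    """Quadratic Gotoh dynamic program for global affine-gap alignment."""
    n, m = len(a), len(b)
    neg = float("-inf")
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = open_ + (i - 1) * ext
    for j in range(1, m + 1):
        Y[0][j] = open_ + (j - 1) * ext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + ext,
                          Y[i - 1][j] + open_)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + ext,
                          X[i][j - 1] + open_)
    return max(M[n][m], X[n][m], Y[n][m])


def classify_sequence(seq: str, ref: AmpliconRef, read_id: str = "r"):
    return classify_read(align_to_amplicon(seq, ref), ref, read_id)


class TestMedianQualityFilter:
    def _read(self, quals):
        return FastqRead("r", "A" * len(quals), tuple(quals))

    def test_all_q5_removed(self):
        retained, discarded = filter_reads_by_median_quality([self._read([5] * 30)])
        assert retained == []
        assert discarded[0][1] == 5

    def test_all_q6_retained(self):
        retained, discarded = filter_reads_by_median_quality([self._read([6] * 30)])
        assert len(retained) == 1
        assert discarded == []

    def test_even_length_median_is_mean_of_central_pair(self):
        # sorted [4, 4, 6, 8] -> median 5 -> removed at cutoff 5
        retained, _ = filter_reads_by_median_quality([self._read([6, 4, 8, 4])])
        assert retained == []
        # sorted [4, 4, 8, 8] -> median 6 -> retained
        retained, _ = filter_reads_by_median_quality([self._read([8, 4, 8, 4])])
        assert len(retained) == 1

    @given(st.lists(st.integers(0, 41), min_size=1, max_size=60))
    def test_matches_sort_and_pick_oracle(self, quals):
        retained, _ = filter_reads_by_median_quality([self._read(quals)])
        srt = sorted(quals)
        n = len(srt)
        med = srt[n // 2] if n % 2 else (srt[n // 2 - 1] + srt[n // 2]) / 2
        assert bool(retained) == (med > 5)


class TestAlignToAmplicon:
    def test_reference_read_has_no_events(self, demo_ref):
        result = align_to_amplicon(demo_ref.sequence, demo_ref)
        assert result.events == ()
        assert result.score == len(demo_ref.sequence)

    def test_insertion_between_a_and_t_of_codon(self, demo_ref):
        o = demo_ref.start_codon_offset
        read = demo_ref.sequence[: o + 1] + "A" + demo_ref.sequence[o + 1 :]
        result = align_to_amplicon(read, demo_ref)
        assert len(result.events) == 1
        ev = result.events[0]
        assert (ev.kind, ev.length, ev.bases) == ("ins", 1, "A")
        # canonical placement is left-aligned, but the equivalence range must
        # include the between-A-and-T position
        left, right = insertion_placement_range(
            demo_ref.sequence, ev.position, ev.bases
        )
        assert left <= o + 1 <= right

    def test_t_insertion_sits_exactly_between_a_and_t(self, demo_ref):
        o = demo_ref.start_codon_offset
        read = demo_ref.sequence[: o + 1] + "T" + demo_ref.sequence[o + 1 :]
        result = align_to_amplicon(read, demo_ref)
        ev = result.events[0]
        assert ev.position == o + 1
        assert ev.bases == "T"

    def test_deletion_left_aligned_in_homopolymer(self):
        ref = AmpliconRef("ATGAAAACCC" + "G" * 20, 0)
        read = "ATGAAACCC" + "G" * 20  # one A of the run removed
        result = align_to_amplicon(read, ref)
        ev = result.events[0]
        assert (ev.kind, ev.length) == ("del", 1)
        assert ev.position == 3  # leftmost A of the homopolymer

    def test_empty_and_short_reads_rejected(self, demo_ref):
        with pytest.raises(ValueError):
            align_to_amplicon("", demo_ref)
        with pytest.raises(ValueError):
            align_to_amplicon("ACGTACGT", demo_ref)

    @settings(max_examples=40, deadline=None)
    @given(st.data())
    def test_score_matches_dp_oracle(self, data):
        rng_seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(rng_seed)
        ref_seq = "ATG" + "".join(rng.choice(list("ACGT"), size=50))
        read = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 60))))
        ref = AmpliconRef(ref_seq, 0)
        result = align_to_amplicon(read, ref)
        assert result.score == pytest.approx(
            affine_score_oracle(ref_seq, read)
        )

    def test_score_matches_oracle_on_edited_reads(self, demo_ref):
        o = demo_ref.start_codon_offset
        reads = [
            demo_ref.sequence[: o + 1] + "G" + demo_ref.sequence[o + 1 :],
            demo_ref.sequence[:o] + demo_ref.sequence[o + 2 :],  # 2 bp del
        ]
        for read in reads:
            result = align_to_amplicon(read, demo_ref)
            assert result.score == pytest.approx(
                affine_score_oracle(demo_ref.sequence, read)
            )


class TestClassifyRead:
    def test_unedited(self, demo_ref):
        outcome = classify_sequence(demo_ref.sequence, demo_ref)
        assert outcome.category == "no_change"

    def test_two_bp_deletion_spanning_codon(self, demo_ref):
        o = demo_ref.start_codon_offset
        read = demo_ref.sequence[:o] + demo_ref.sequence[o + 2 :]
        outcome = classify_sequence(read, demo_ref)
        assert outcome.category == "deletion"
        assert sum(e.length for e in outcome.events if e.kind == "del") == 2

    def test_mixed_events_go_to_larger(self, demo_ref):
        o = demo_ref.start_codon_offset
        # 1-bp insertion at the codon plus a 3-bp deletion a few bases right
        seq = demo_ref.sequence
        read = seq[: o + 1] + "G" + seq[o + 1 : o + 6] + seq[o + 9 :]
        outcome = classify_sequence(read, demo_ref)
        assert outcome.category == "deletion"

    def test_tie_goes_to_insertion(self, demo_ref):
        o = demo_ref.start_codon_offset
        seq = demo_ref.sequence
        read = seq[: o + 1] + "G" + seq[o + 1 : o + 6] + seq[o + 7 :]
        outcome = classify_sequence(read, demo_ref)
        ins = sum(e.length for e in outcome.events if e.kind == "ins")
        del_ = sum(e.length for e in outcome.events if e.kind == "del")
        assert ins == del_ == 1
        assert outcome.category == "insertion"

    def test_events_outside_window_ignored(self, demo_ref):
        seq = demo_ref.sequence
        read = seq[:10] + seq[12:]  # 2-bp deletion far from the codon
        outcome = classify_sequence(read, demo_ref)
        assert outcome.category == "no_change"

    def test_truncated_read_discarded(self, demo_ref):
        lo, hi = demo_ref.target_window
        read = demo_ref.sequence[: lo + 5]  # stops inside the window
        outcome = classify_read(
            AlignmentResult(0.0, (), (0, lo + 5)), demo_ref, "r"
        )
        assert outcome.category == "discarded"
        assert outcome.reason == "truncated"


class TestIndelSummary:
    def test_reference_sample_percentages(self):
        s = IndelSummary.from_counts(87_554, 68_228, 16_378, 2_948)
        assert round(s.pct_no_change, 1) == 77.9
        assert round(s.pct_insertion, 1) == 18.7
        assert round(s.pct_deletion, 1) == 3.4
        assert round(s.pct_indel, 1) == 22.1
        assert s.n_indel == 19_326

    def test_partition(self):
        s = IndelSummary.from_counts(100, 70, 20, 10)
        assert s.pct_no_change + s.pct_indel == pytest.approx(100.0)
        assert s.pct_insertion + s.pct_deletion == pytest.approx(s.pct_indel)

    def test_all_no_change(self):
        s = IndelSummary.from_counts(50, 50, 0, 0)
        assert s.pct_indel == 0.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            IndelSummary.from_counts(100, 50, 20, 10)

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError):
            indel_summary([])

    def test_from_outcomes_matches_truth_spectrum(self, demo_ref):
        o = demo_ref.start_codon_offset
        n = 8000
        p_ins, p_del = 0.15, 0.05
        spec = AmpliconSpec(
            demo_ref.sequence, o,
            {
                IndelEvent("ins", o + 1, 1, "A"): p_ins,
                IndelEvent("del", o, 2): p_del,
            },
            n, seed=11,
        )
        reads = simulate_amplicon_reads(spec)
        outcomes = [classify_sequence(r.sequence, demo_ref, r.name) for r in reads]
        s = indel_summary(outcomes)
        assert s.total_reads == n
        se = math.sqrt((p_ins + p_del) * (1 - p_ins - p_del) / n)
        assert abs(s.pct_indel / 100 - (p_ins + p_del)) <= 3 * se
        # classification must agree with per-read truth exactly (no noise)
        truth_ins = sum(1 for r in reads if r.event and r.event.kind == "ins")
        truth_del = sum(1 for r in reads if r.event and r.event.kind == "del")
        assert s.n_insertion == truth_ins
        assert s.n_deletion == truth_del


class TestSizeSpectrum:
    def test_single_length_mass(self, demo_ref):
        o = demo_ref.start_codon_offset
        spec = AmpliconSpec(
            demo_ref.sequence, o,
            {IndelEvent("ins", o + 1, 1, "A"): 0.2}, 3000, seed=4,
        )
        reads = simulate_amplicon_reads(spec)
        outcomes = [classify_sequence(r.sequence, demo_ref, r.name) for r in reads]
        ins_hist, del_hist = size_spectrum(outcomes)
        assert set(ins_hist) == {1}
        assert del_hist == {}
        s = indel_summary(outcomes)
        assert ins_hist[1] == pytest.approx(s.pct_insertion)

    def test_conservation_against_summary(self, demo_ref):
        o = demo_ref.start_codon_offset
        spec = AmpliconSpec(
            demo_ref.sequence, o,
            {
                IndelEvent("ins", o + 1, 1, "A"): 0.1,
                IndelEvent("ins", o + 1, 2, "AT"): 0.05,
                IndelEvent("del", o, 2): 0.04,
                IndelEvent("del", o - 1, 4): 0.02,
            },
            4000, seed=5,
        )
        reads = simulate_amplicon_reads(spec)
        outcomes = [classify_sequence(r.sequence, demo_ref, r.name) for r in reads]
        ins_hist, del_hist = size_spectrum(outcomes)
        s = indel_summary(outcomes)
        assert sum(ins_hist.values()) == pytest.approx(s.pct_insertion)
        assert sum(del_hist.values()) == pytest.approx(s.pct_deletion)


class TestInsertionBaseComposition:
    def test_reference_counts(self):
        comp = InsertionComposition.from_counts(7925, 6703, 230, 797)
        assert comp.total == 15_655
        assert round(comp.percentage("A"), 1) == 50.6
        assert round(comp.percentage("T"), 1) == 42.8
        assert round(comp.percentage("G"), 1) == 1.5
        assert round(comp.percentage("C"), 1) == 5.1

    def test_empty_composition_has_no_percentages(self):
        comp = InsertionComposition.from_counts(0, 0, 0, 0)
        assert comp.total == 0
        with pytest.raises(ValueError):
            comp.percentage("A")

    def test_recovers_configured_proportions(self, demo_ref):
        o = demo_ref.start_codon_offset
        props = {"A": 0.487, "T": 0.446, "G": 0.018, "C": 0.049}
        rate = 0.3
        spectrum = {
            IndelEvent("ins", o + 1, 1, b): rate * p for b, p in props.items()
        }
        spec = AmpliconSpec(demo_ref.sequence, o, spectrum, 12_000, seed=6)
        reads = simulate_amplicon_reads(spec)
        outcomes = [classify_sequence(r.sequence, demo_ref, r.name) for r in reads]
        comp = insertion_base_composition(outcomes, demo_ref)
        for base, p in props.items():
            se = math.sqrt(p * (1 - p) / comp.total)
            assert abs(comp.percentage(base) / 100 - p) <= 3 * se
        # every truth single insertion must be counted
        truth = sum(1 for r in reads if r.event is not None)
        assert comp.total == truth

    def test_multi_base_insertions_not_counted(self, demo_ref):
        o = demo_ref.start_codon_offset
        read = (demo_ref.sequence[: o + 1] + "AT" + demo_ref.sequence[o + 1 :])
        outcome = classify_sequence(read, demo_ref)
        assert outcome.category == "insertion"
        comp = insertion_base_composition([outcome], demo_ref)
        assert comp.total == 0


class TestKozakAssessment:
    CONTEXT = "AAAGACGCCATGCTTAAA"  # ATG at offset 9, -3 base G

    def _ref(self):
        return AmpliconRef(self.CONTEXT, 9)

    def test_a_insertion_creates_cryptic_atg_with_c_minus3(self):
        ref = self._ref()
        call = kozak_assessment(IndelEvent("ins", 10, 1, "A"), ref)
        assert call.cryptic_atg_present
        assert call.minus3_base == "C"
        assert not call.kozak_favorable

    def test_unedited_reference_is_favorable(self):
        call = kozak_assessment(None, self._ref())
        assert call.cryptic_atg_present
        assert call.new_atg_offset == 9
        assert call.minus3_base == "G"
        assert call.kozak_favorable

    def test_g_insertion_destroys_atg(self):
        call = kozak_assessment(IndelEvent("ins", 10, 1, "G"), self._ref())
        assert not call.cryptic_atg_present
        assert call.minus3_base is None

    def test_t_insertion_shifts_codon(self):
        # A T TG -> no ATG within reach?  ..CCA T TGC: scan finds nothing
        call = kozak_assessment(IndelEvent("ins", 10, 1, "T"), self._ref())
        # reconstructed: AAAGACGCCA T TGCTTAAA -> ATTG, no ATG nearby
        assert not call.cryptic_atg_present

    def test_rejects_non_insertion_events(self):
        with pytest.raises(ValueError):
            kozak_assessment(IndelEvent("del", 9, 1), self._ref())
        with pytest.raises(ValueError):
            kozak_assessment(IndelEvent("ins", 2, 1, "A"), self._ref())


class TestFastqRoundTrip:
    def test_write_then_read(self, tmp_path, demo_ref):
        o = demo_ref.start_codon_offset
        spec = AmpliconSpec(
            demo_ref.sequence, o,
            {IndelEvent("ins", o + 1, 1, "T"): 0.5}, 100, seed=8,
        )
        reads = simulate_amplicon_reads(spec)
        path = tmp_path / "reads.fastq"
        write_fastq(reads, path)
        back = list(read_fastq(path))
        assert len(back) == 100
        assert [r.sequence for r in back] == [r.sequence for r in reads]
        assert [r.qualities for r in back] == [r.qualities for r in reads]
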