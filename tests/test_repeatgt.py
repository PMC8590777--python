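import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from replongmeth.io_model import AlignedRead, GenomicInterval
from replongmeth.repeatgt import (
    EXPANDED,
    NON_EXPANDED,
    RepeatCall,
    RepeatLocus,
    SpanningError,
    allele_summary,
    copy_number_change,
    decompose_repeat,
    disease_range_classify,
    extract_repeat_tract,
    genotype_reads,
    phase_by_copy_number,
    reconstruct,
    waterfall_table,
)

LOCUS = RepeatLocus(
    interval=GenomicInterval("c", 500, 539), unit="GGC", ref_copies=13, flank_margin=100
)


def spanning_read(read_id="r", insert=0, delete=0):
    """A read spanning the locus: 600 bp left flank, repeat, right flank,
    with a net indel placed inside the repeat."""
    parts = [("M", 520)]
    if insert:
        parts += [("I", insert)]
    if delete:
        parts += [("D", delete), ("M", 19 - delete + 600)]
    else:
        parts += [("M", 19 + 600)]
    qlen = sum(n for op, n in parts if op in "MIS")
    return AlignedRead(
        read_id=read_id, chrom="c", ref_start=0, strand="+",
        cigar=parts, seq="A" * qlen, mod_scores={},
    )


class TestCopyNumber:
    def test_240_base_insertion_gives_93_copies(self):
        call = copy_number_change(spanning_read(insert=240), LOCUS)
        assert call.rel_change == 80
        assert call.abs_copies == 93

    def test_reference_matching_read_is_13_copies(self):
        call = copy_number_change(spanning_read(), LOCUS)
        assert (call.rel_change, call.abs_copies) == (0, 13)

    def test_nine_base_deletion_is_minus_three(self):
        assert copy_number_change(spanning_read(delete=9), LOCUS).rel_change == -3

    def test_fractional_change_rounds_half_away_from_zero(self):
        assert copy_number_change(spanning_read(insert=5), LOCUS).rel_change == 2
        assert copy_number_change(spanning_read(delete=5), LOCUS).rel_change == -2

    def test_indel_outside_margin_ignored(self):
        read = AlignedRead(
            "r", "c", 0, "+", [("M", 200), ("I", 30), ("M", 939)], "A" * 1169, {}
        )
        assert copy_number_change(read, LOCUS).rel_change == 0

    def test_non_spanning_read_rejected_and_counted(self):
        short = AlignedRead("s", "c", 450, "+", [("M", 200)], "A" * 200, {})
        with pytest.raises(SpanningError, match="s"):
            copy_number_change(short, LOCUS)
        calls, rejected = genotype_reads([spanning_read(), short], LOCUS)
        assert len(calls) == 1 and rejected == ["s"]


class TestPhasing:
    def test_threshold_boundary(self):
        calls = [RepeatCall("a", 49, 62), RepeatCall("b", 50, 63)]
        groups = phase_by_copy_number(calls)
        assert [c.read_id for c in groups[NON_EXPANDED]] == ["a"]
        assert [c.read_id for c in groups[EXPANDED]] == ["b"]

    def test_all_below_threshold(self):
        groups = phase_by_copy_number([RepeatCall("a", 0, 13)])
        assert groups[EXPANDED] == []

    def test_mixture_partition_exhaustive_disjoint(self):
        calls = [RepeatCall(str(i), rc, rc + 13) for i, rc in enumerate([0, 0, 80, 120])]
        groups = phase_by_copy_number(calls)
        assert len(groups[NON_EXPANDED]) == 2 and len(groups[EXPANDED]) == 2
        ids = [c.read_id for g in groups.values() for c in g]
        assert sorted(ids) == sorted(c.read_id for c in calls)

    @given(st.integers(min_value=-13, max_value=400))
    def test_monotone_in_rel_change(self, rel):
        group_of = lambda r: (
            EXPANDED if phase_by_copy_number([RepeatCall("x", r, max(0, r + 13))])[EXPANDED] else NON_EXPANDED
        )
        if group_of(rel) == EXPANDED:
            assert group_of(rel + 1) == EXPANDED


class TestAlleleSummary:
    def test_singleton(self):
        s = allele_summary("g", [RepeatCall("a", 80, 93)])
        assert (s.median, s.sd, s.iqr) == (93, 0.0, 0.0)
        assert not s.sd_defined

    def test_closed_form_small_sample(self):
        calls = [RepeatCall(str(i), v - 13, v) for i, v in enumerate([1, 2, 3, 4])]
        s = allele_summary("g", calls)
        assert s.median == 2.5
        assert s.sd == pytest.approx(1.2909944, abs=1e-6)
        assert s.iqr == pytest.approx(1.5)

    def test_identical_values(self):
        calls = [RepeatCall(str(i), 0, 13) for i in range(5)]
        s = allele_summary("g", calls)
        assert (s.sd, s.iqr) == (0.0, 0.0)

    def test_agrees_with_brute_force_reference(self):
        """Median/SD/IQR against a from-first-principles implementation
        on random samples."""
        rng = np.random.default_rng(7)

        def quantile(sorted_vals, q):
            h = (len(sorted_vals) - 1) * q
            lo, hi = int(np.floor(h)), int(np.ceil(h))
            return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])

        for _ in range(25):
            vals = rng.integers(0, 700, size=int(rng.integers(2, 101))).tolist()
            calls = [RepeatCall(str(i), v - 13, v) for i, v in enumerate(vals)]
            s = allele_summary("g", calls)
            sv = sorted(float(v) for v in vals)
            mean = sum(sv) / len(sv)
            sd = (sum((v - mean) ** 2 for v in sv) / (len(sv) - 1)) ** 0.5
            assert s.median == pytest.approx(quantile(sv, 0.5), abs=1e-9)
            assert s.sd == pytest.approx(sd, abs=1e-9)
            assert s.iqr == pytest.approx(quantile(sv, 0.75) - quantile(sv, 0.25), abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            allele_summary("g", [])


class TestDiseaseRange:
    @pytest.mark.parametrize(
        "copies,label",
        [
            (13, "normal"),
            (40, "normal"),
            (41, "disease-causing range"),
            (140, "disease-causing range"),
            (300, "disease-causing range"),
            (301, "beyond range"),
            (522, "beyond range"),
        ],
    )
    def test_classification(self, copies, label):
        assert disease_range_classify(copies) == label


INSERTION = "ACCGAGAAGATGCCCGCCCTGC"


class TestDecomposition:
    def test_unit_then_interruption(self):
        comp = decompose_repeat("GGCGGCGGA", "GGC", {"GGA"})
        assert comp.runs == (("GGC", 2), ("GGA", 1))

    def test_pure_repeat(self):
        assert decompose_repeat("GGCGGCGGCGGC", "GGC").runs == (("GGC", 4),)

    def test_named_insertion_priority(self):
        comp = decompose_repeat("GGC" + INSERTION + "GGC", "GGC", {"GGA"}, {INSERTION})
        assert comp.runs == (("GGC", 1), ("INS:" + INSERTION, 1), ("GGC", 1))

    def test_other_bases_fall_through(self):
        comp = decompose_repeat("GGCTTGGC", "GGC", {"GGA"})
        assert reconstruct(comp) == "GGCTTGGC"

    @settings(max_examples=300, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=60))
    def test_reconstruction_identity(self, seq):
        comp = decompose_repeat(seq, "GGC", {"GGA"}, {INSERTION})
        assert reconstruct(comp) == seq
        assert comp.total_len == len(seq)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            decompose_repeat("", "GGC")


class TestWaterfall:
    def test_rows_sorted_by_length_descending(self):
        comps = [
            decompose_repeat("GGC" * 10, "GGC", read_id="short"),
            decompose_repeat("GGC" * 100, "GGC", read_id="long"),
        ]
        table = waterfall_table(comps)
        assert list(table[table["row"] == 0]["read_id"].unique()) == ["long"]

    def test_empty_input(self):
        assert len(waterfall_table([])) == 0

    def test_segment_offsets_are_cumulative(self):
        seq = "GGC" * 4 + "GGA" + "GGC" * 2
        comp = decompose_repeat(seq, "GGC", {"GGA"}, read_id="r")
        table = waterfall_table([comp], interruptions={"GGA"})
        starts = table["start"].tolist()
        lengths = table["length"].tolist()
        expect = np.concatenate([[0], np.cumsum(lengths)[:-1]])
        assert starts == expect.tolist()
        assert sum(lengths) == len(seq)
        assert table["cls"].tolist() == ["unit", "interruption", "unit"]


class TestTractExtraction:
    def test_expanded_read_tract_includes_insertion(self):
        read = spanning_read(insert=6)
        read = AlignedRead(
            read.read_id, "c", 0, "+", read.cigar,
            "A" * 500 + "GGC" * 13 + "TTTTTT" + "A" * 600, {},
        )
        tract = extract_repeat_tract(read, LOCUS)
        assert tract == "GGC" * 13 + "TTTTTT"
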