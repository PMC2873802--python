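"""Coordinate algebra against brute-force per-base oracles."""

import pytest

from lrgkit import coord_map, fixtures
from lrgkit.coord_map import CDS, UTR3, UTR5, CodingPosition
from lrgkit.core_model import AssemblyMapping, LegacyMap, MappingSpan, SeqDiff
from lrgkit.errors import (
    NonCodingTranscriptError,
    OffsetConventionError,
    OutOfSpanError,
    UnmappablePositionError,
)


# ---------------------------------------------------------------------------
# g. <-> c.
# ---------------------------------------------------------------------------

class TestGToC:
    def test_worked_example_intron_offset(self, col1a1_record):
        # 35 coding exons of 69 nt + one of 36 put exon 36's donor at c.2451
        t = col1a1_record.fixed.transcripts[0]
        donor = t.exons[35].lrg_end
        c = coord_map.g_to_c(t, donor + 77)
        assert (c.region, c.anchor, c.intron_offset) == (CDS, 2451, 77)

    def test_cds_start(self, col1a1_record):
        t = col1a1_record.fixed.transcripts[0]
        c = coord_map.g_to_c(t, t.coding_region.cds_start)
        assert c == CodingPosition(CDS, 1)

    def test_out_of_span(self, col1a1_record):
        t = col1a1_record.fixed.transcripts[0]
        with pytest.raises(OutOfSpanError):
            coord_map.g_to_c(t, t.span_start - 1)
        with pytest.raises(OutOfSpanError):
            coord_map.g_to_c(t, t.span_end + 1)

    def test_noncoding_transcript_refused(self, small_gene):
        record, _ = small_gene
        t = record.fixed.transcripts[0]
        stripped = fixtures.build_record(
            record.lrg_id, record.fixed.sequence,
            [fixtures.TranscriptSpec([(e.lrg_start, e.lrg_end)
                                      for e in t.exons])])
        with pytest.raises(NonCodingTranscriptError):
            coord_map.g_to_c(stripped.fixed.transcripts[0], t.span_start)

    @pytest.mark.parametrize("seed", range(20))
    def test_exhaustive_against_oracle(self, seed):
        """Every base of the transcript span matches the naive labeling walk
        and round-trips; acceptance property over >= 20 random fixtures."""
        record, tables = fixtures.make_synthetic_gene(
            fixtures.GeneModelSpec(seed=seed,
                                   assembly_strand=-1 if seed % 2 else 1))
        t = record.fixed.transcripts[0]
        for g in range(t.span_start, t.span_end + 1):
            c = coord_map.g_to_c(t, g)
            assert c == tables.g_to_c[g], (seed, g)
            assert coord_map.c_to_g(t, c) == g, (seed, g)

    def test_intron_offset_balance(self, small_gene):
        """'+' and '-' labels in an intron differ in count by at most 1."""
        record, _ = small_gene
        t = record.fixed.transcripts[0]
        for left, right in zip(t.exons, t.exons[1:]):
            plus = minus = 0
            for g in range(left.lrg_end + 1, right.lrg_start):
                off = coord_map.g_to_c(t, g).intron_offset
                assert off != 0
                if off > 0:
                    plus += 1
                else:
                    minus += 1
            assert abs(plus - minus) <= 1


class TestCToG:
    def test_anchor_one(self, col1a1_record):
        t = col1a1_record.fixed.transcripts[0]
        assert coord_map.c_to_g(t, CodingPosition(CDS, 1)) == \
            t.coding_region.cds_start

    def test_worked_example_position(self, col1a1_record):
        t = col1a1_record.fixed.transcripts[0]
        g = coord_map.c_to_g(t, CodingPosition(CDS, 2451, 77))
        assert g == t.exons[35].lrg_end + 77

    def test_offset_past_midpoint_refused(self, col1a1_record):
        t = col1a1_record.fixed.transcripts[0]
        # introns are 250 nt: +126 belongs to the downstream boundary
        with pytest.raises(OffsetConventionError):
            coord_map.c_to_g(t, CodingPosition(CDS, 2451, 126))
        with pytest.raises(OffsetConventionError):
            coord_map.c_to_g(t, CodingPosition(CDS, 2452, -126))

    def test_offset_beyond_intron_refused(self, col1a1_record):
        t = col1a1_record.fixed.transcripts[0]
        with pytest.raises(OutOfSpanError):
            coord_map.c_to_g(t, CodingPosition(CDS, 2451, 400))

    def test_offset_from_non_boundary_refused(self, col1a1_record):
        t = col1a1_record.fixed.transcripts[0]
        with pytest.raises(OffsetConventionError):
            coord_map.c_to_g(t, CodingPosition(CDS, 572, 1))

    def test_utr_anchors(self, col1a1_record):
        t = col1a1_record.fixed.transcripts[0]
        assert coord_map.c_to_g(t, CodingPosition(UTR5, -1)) == \
            t.coding_region.cds_start - 1
        g_star1 = coord_map.c_to_g(t, CodingPosition(UTR3, 1))
        assert coord_map.g_to_c(t, g_star1) == CodingPosition(UTR3, 1)


class TestCToP:
    @pytest.mark.parametrize("anchor,residue", [
        (572, 191),  # the worked example
        (1, 1), (3, 1), (4, 2),
    ])
    def test_codon_arithmetic(self, anchor, residue):
        assert coord_map.c_to_p(CodingPosition(CDS, anchor)) == residue

    def test_consistent_with_codon_span(self):
        from lrgkit.seq_ops import codon_span
        for n in range(1, 400):
            for anchor in codon_span(n):
                assert coord_map.c_to_p(CodingPosition(CDS, anchor)) == n

    def test_utr_and_intronic_refused(self):
        with pytest.raises(OutOfSpanError):
            coord_map.c_to_p(CodingPosition(UTR5, -4))
        with pytest.raises(OutOfSpanError):
            coord_map.c_to_p(CodingPosition(CDS, 10, 5))


# ---------------------------------------------------------------------------
# record <-> assembly
# ---------------------------------------------------------------------------

def expand_span_per_base(span):
    """Independent oracle: expand a span + diffs into a per-base table by
    simulating the alignment column by column."""
    table = {}
    lrg_positions = list(range(span.lrg_start, span.lrg_end + 1))
    # build the gapped alignment as (lrg_pos | None, other_offset | None)
    events = sorted(span.diffs, key=lambda d: (d.lrg_start, d.other_start))
    columns = []
    inserts_at = {}
    skip = set()
    for d in events:
        if d.kind == "lrg_insertion":
            skip.update(range(d.lrg_start, d.lrg_end + 1))
        elif d.kind == "other_insertion":
            inserts_at[d.lrg_start] = d.other_end - d.other_start + 1
    for g in lrg_positions:
        for _ in range(inserts_at.get(g, 0)):
            columns.append(None)  # other-only column
        columns.append(g if g not in skip else "gap")
    # assign other coordinates to columns
    if span.strand == 1:
        o = span.other_start
        for col in columns:
            if col == "gap":
                continue  # lrg-only column consumes no other base
            if col is None:
                o += 1
                continue
            table[col] = (o, 1)
            o += 1
    else:
        o = span.other_end
        for col in columns:
            if col == "gap":
                continue
            if col is None:
                o -= 1
                continue
            table[col] = (o, -1)
            o -= 1
    return table


class TestAssemblyMapping:
    def test_reverse_span_worked_example(self, col1a1_record):
        mapping = col1a1_record.updatable.annotation_sets[0].mappings[0]
        m = coord_map.map_lrg_to_other(mapping, 1)
        assert (m.accession, m.position, m.strand) == (
            "NT_010783.15", 13553152, -1)
        # oracle: enumerate the printed span base by base
        span = mapping.spans[0]
        table = expand_span_per_base(span)
        assert table[1] == (13553152, -1)
        assert table[span.lrg_end] == (13535609, -1)
        assert coord_map.map_lrg_to_other(mapping, span.lrg_end).position == \
            13535609

    def test_identity_forward_span(self):
        mapping = AssemblyMapping("A", "CT_1.1",
                                  [MappingSpan(1, 100, 1, 100, 1)])
        for k in (1, 42, 100):
            assert coord_map.map_lrg_to_other(mapping, k).position == k

    def test_uncovered_position(self):
        mapping = AssemblyMapping("A", "CT_1.1",
                                  [MappingSpan(10, 20, 110, 120, 1)])
        with pytest.raises(UnmappablePositionError, match="10..20"):
            coord_map.map_lrg_to_other(mapping, 5)

    @pytest.mark.parametrize("strand", [1, -1])
    def test_spans_with_diffs_match_oracle(self, strand):
        # 1..60 against a target with: mismatch at lrg 11..12, a 4 nt
        # record-only insertion at lrg 21..24, a 3 nt target-only insertion
        # between lrg 40 and 41
        diffs = [
            SeqDiff("mismatch", 11, 12, 0, 0, "AT", "GC"),
            SeqDiff("lrg_insertion", 21, 24, 0, -1, "ACGT", ""),
            SeqDiff("other_insertion", 41, 40, 0, 2, "", "GGG"),
        ]
        other_len = 60 - 4 + 3
        if strand == 1:
            span = MappingSpan(1, 60, 1001, 1000 + other_len, 1, diffs)
            # fix up diff other-side coordinates for the oracle's benefit
            diffs[0].other_start, diffs[0].other_end = 1011, 1012
            diffs[2].other_start, diffs[2].other_end = 1037, 1039
        else:
            span = MappingSpan(1, 60, 1001, 1000 + other_len, -1, diffs)
            diffs[0].other_start, diffs[0].other_end = 1048, 1049
            diffs[2].other_start, diffs[2].other_end = 1021, 1023
        mapping = AssemblyMapping("A", "CT_9.9", [span])
        table = expand_span_per_base(span)

        for g in range(1, 61):
            if 21 <= g <= 24:
                with pytest.raises(UnmappablePositionError) as exc:
                    coord_map.map_lrg_to_other(mapping, g)
                assert exc.value.flanks == (20, 25)
                continue
            m = coord_map.map_lrg_to_other(mapping, g)
            assert (m.position, m.strand) == table[g], g
            assert coord_map.map_other_to_lrg(mapping, "CT_9.9",
                                              m.position) == g

    def test_target_insertion_unmappable_back(self):
        diffs = [SeqDiff("other_insertion", 11, 10, 115, 117, "", "AAA")]
        span = MappingSpan(1, 20, 105, 127, 1, diffs)
        mapping = AssemblyMapping("A", "CT_2.1", [span])
        with pytest.raises(UnmappablePositionError, match="target-side"):
            coord_map.map_other_to_lrg(mapping, "CT_2.1", 116)

    def test_wrong_accession(self):
        mapping = AssemblyMapping("A", "CT_1.1", [MappingSpan(1, 5, 1, 5, 1)])
        with pytest.raises(UnmappablePositionError, match="CT_1.1"):
            coord_map.map_other_to_lrg(mapping, "XX_0.0", 3)

    @pytest.mark.parametrize("seed", range(6))
    def test_bijection_on_fixture_mappings(self, seed):
        record, tables = fixtures.make_synthetic_gene(
            fixtures.GeneModelSpec(seed=seed,
                                   assembly_strand=-1 if seed % 2 else 1))
        mapping = record.updatable.annotation_sets[0].mappings[0]
        for g, (o, strand) in tables.assembly.items():
            m = coord_map.map_lrg_to_other(mapping, g)
            assert (m.position, m.strand) == (o, strand)
            assert coord_map.map_other_to_lrg(mapping, mapping.other_accession,
                                              o) == g


# ---------------------------------------------------------------------------
# legacy numbering
# ---------------------------------------------------------------------------

class TestLegacyNumbering:
    def test_label_lookup(self):
        lm = LegacyMap("old", {1: "1", 2: "2A", 3: "2B"})
        got = coord_map.legacy_exon_label(lm, 3)
        assert (got.label, got.systematic_fallback) == ("2B", False)

    def test_systematic_fallback(self):
        lm = LegacyMap("old", {})
        got = coord_map.legacy_exon_label(lm, 5)
        assert (got.label, got.systematic_fallback) == ("5", True)

    def test_reverse_lookup_round_trip(self):
        lm = LegacyMap("old", {1: "1", 2: "2A", 3: "2B", 4: "3"})
        inverse = {v: k for k, v in lm.exon_labels.items()}
        assert len(inverse) == len(lm.exon_labels)  # labels unique
        for ordinal in lm.exon_labels:
            assert inverse[coord_map.legacy_exon_label(lm, ordinal).label] == \
                ordinal

    def test_residue_shift(self):
        lm = LegacyMap("mature", residue_shifts=[(24, 500, 23)])
        assert coord_map.legacy_residue_number(lm, 24) == (1, "mature")

    def test_residue_outside_ranges(self):
        lm = LegacyMap("mature", residue_shifts=[(24, 500, 23)])
        with pytest.raises(OutOfSpanError, match="24..500"):
            coord_map.legacy_residue_number(lm, 23)

    @pytest.mark.parametrize("seed", range(5))
    def test_randomized_shifts_against_subtraction(self, seed):
        import random
        rng = random.Random(seed)
        cursor = 1
        shifts = []
        for _ in range(4):
            start = cursor + rng.randrange(0, 5)
            end = start + rng.randrange(5, 50)
            shifts.append((start, end, rng.randrange(-30, 30)))
            cursor = end + 1
        lm = LegacyMap("rand", residue_shifts=shifts)
        for start, end, shift in shifts:
            for residue in range(start, end + 1):
                legacy, scheme = coord_map.legacy_residue_number(lm, residue)
                assert legacy == residue - shift  # the oracle is subtraction
                assert scheme == "rand"
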