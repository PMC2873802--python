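"""Construct valid records from parts and generate synthetic test genes.

``build_record`` derives every redundant fixed-layer field (cDNA markup,
spliced sequence, protein) from a genomic sequence plus exon intervals and
CDS bounds, so that the result always passes :func:`validate_record`.

``make_synthetic_gene`` produces a seeded random gene together with
*truth tables*: exhaustive per-base genomic<->coding labels, a per-base
assembly correspondence and a per-residue codon map, each computed by an
independent naive walk so they can serve as oracles for the arithmetic in
:mod:`lrgkit.coord_map`.

``make_col1a1_like`` engineers a single record on which the classic worked
examples all hold at once: a 36th coding exon ending at c.2451 (35 exons of
69 coding nt plus one of 36), codon 191 = GGC so c.572G>C is a Gly->Ala
change, a reverse-strand placement against contig bases 13535609..13553152,
and identical-frame cross-references.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from . import seq_ops
from .coord_map import CDS, UTR3, UTR5, CodingPosition
from .core_model import (
    AnnotationSet,
    AssemblyMapping,
    CodingRegion,
    CrossReference,
    Exon,
    FixedAnnotation,
    LegacyMap,
    LrgRecord,
    MappingSpan,
    ProteinProduct,
    Transcript,
    UpdatableAnnotation,
)
from .errors import LrgError

_BASES = "ACGT"
_NONSTOP_CODONS = sorted(set(seq_ops.STANDARD_CODE) - seq_ops.STOP_CODONS)


# ---------------------------------------------------------------------------
# deterministic record assembly
# ---------------------------------------------------------------------------

@dataclass
class TranscriptSpec:
    """Raw material for one transcript: exon intervals plus CDS bounds."""

    exon_intervals: Sequence[Tuple[int, int]]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None


def build_record(
    lrg_id: str,
    genomic_seq: str,
    transcripts_spec: Sequence[TranscriptSpec],
    *,
    organism: str = "Homo sapiens",
    taxon_id: int = 9606,
) -> LrgRecord:
    """Assemble a record, deriving cDNA/protein content from the genome.

    Raises on overlapping exons, out-of-frame CDS, internal stop codons or
    a missing terminal stop -- the returned record always validates clean.
    """
    seq_ops.check_alphabet(genomic_seq)
    transcripts = []
    for k, tspec in enumerate(transcripts_spec, start=1):
        transcripts.append(_build_transcript(f"t{k}", genomic_seq, tspec))
    fixed = FixedAnnotation(sequence=genomic_seq, transcripts=transcripts,
                            organism=organism, taxon_id=taxon_id)
    return LrgRecord(lrg_id=lrg_id, fixed=fixed,
                     updatable=UpdatableAnnotation())


def _build_transcript(name: str, genomic: str, tspec: TranscriptSpec) -> Transcript:
    prev_end = 0
    cdna_cursor = 0
    exons: List[Exon] = []
    for start, end in tspec.exon_intervals:
        if end < start:
            raise LrgError(f"exon end {end} < start {start}")
        if start <= prev_end:
            raise LrgError(f"exon {start}..{end} overlaps or precedes previous "
                           f"exon ending at {prev_end}")
        if start < 1 or end > len(genomic):
            raise LrgError(f"exon {start}..{end} outside sequence "
                           f"1..{len(genomic)}")
        length = end - start + 1
        exons.append(Exon(start, end, cdna_cursor + 1, cdna_cursor + length))
        prev_end = end
        cdna_cursor += length

    cdna = seq_ops.splice(genomic, exons)
    coding_region = None
    protein = None
    if tspec.cds_start is not None:
        if tspec.cds_end is None:
            raise LrgError("cds_start without cds_end")
        if not any(e.lrg_start <= tspec.cds_start <= e.lrg_end for e in exons):
            raise LrgError(f"cds_start {tspec.cds_start} not inside an exon")
        if not any(e.lrg_start <= tspec.cds_end <= e.lrg_end for e in exons):
            raise LrgError(f"cds_end {tspec.cds_end} not inside an exon")
        cds = seq_ops.extract_cds(genomic, exons, tspec.cds_start, tspec.cds_end)
        if len(cds) % 3 != 0:
            raise LrgError(f"exonic CDS length {len(cds)} not a multiple of 3")
        for i in range(0, len(cds) - 3, 3):
            if cds[i:i + 3] in seq_ops.STOP_CODONS:
                raise LrgError(f"internal stop codon at CDS position {i + 1} "
                               f"(codon {i // 3 + 1})")
        protein_seq = seq_ops.translate(cds)
        coding_region = CodingRegion(tspec.cds_start, tspec.cds_end)
        protein = ProteinProduct(name="p" + name[1:], sequence=protein_seq)
        _annotate_peptide_bounds(genomic, exons, coding_region, len(protein_seq))

    return Transcript(name=name, exons=exons, cdna_sequence=cdna,
                      coding_region=coding_region, protein=protein)


def _annotate_peptide_bounds(genomic: str, exons: List[Exon],
                             cr: CodingRegion, protein_len: int) -> None:
    cds_seen = 0
    for exon in exons:
        lo = max(exon.lrg_start, cr.cds_start)
        hi = min(exon.lrg_end, cr.cds_end)
        if lo > hi:
            continue
        first_cds = cds_seen + 1
        cds_seen += hi - lo + 1
        pep_start = (first_cds - 1) // 3 + 1
        pep_end = min((cds_seen - 1) // 3 + 1, protein_len)
        if pep_start <= protein_len:
            exon.peptide_start = pep_start
            exon.peptide_end = pep_end


# ---------------------------------------------------------------------------
# random genes with truth tables
# ---------------------------------------------------------------------------

@dataclass
class GeneModelSpec:
    seed: int = 0
    n_exons: int = 5
    exon_length: Tuple[int, int] = (30, 120)
    intron_length: Tuple[int, int] = (20, 200)
    utr5_length: int = 25
    utr3_length: int = 40
    flank_length: int = 50
    assembly_strand: int = 1
    assembly_offset: int = 1000
    assembly_name: str = "GRCh37"
    other_accession: str = "CT_000001.1"
    lrg_number: int = 900


@dataclass
class TruthTables:
    """Oracle tables computed by naive per-base walks, never by coord_map."""

    #: genomic position -> c. label, for every base of the transcript span
    g_to_c: Dict[int, CodingPosition] = field(default_factory=dict)
    #: genomic position -> (target position, strand) for every mapped base
    assembly: Dict[int, Tuple[int, int]] = field(default_factory=dict)
    #: residue index -> its three CDS anchors
    codons: Dict[int, Tuple[int, int, int]] = field(default_factory=dict)


def _random_cds(rng: random.Random, n_codons: int) -> str:
    body = "".join(rng.choice(_NONSTOP_CODONS) for _ in range(n_codons - 1))
    return body + rng.choice(sorted(seq_ops.STOP_CODONS))


def _paint_cds(genomic: List[str], exons: Sequence[Tuple[int, int]],
               cds_start: int, cds_end: int, cds_seq: str) -> None:
    """Overwrite the exonic bases between the CDS bounds with ``cds_seq``."""
    i = 0
    for start, end in exons:
        lo, hi = max(start, cds_start), min(end, cds_end)
        for g in range(lo, hi + 1):
            genomic[g - 1] = cds_seq[i]
            i += 1
    if i != len(cds_seq):
        raise LrgError("CDS painting mismatch")


def make_synthetic_gene(spec: GeneModelSpec) -> Tuple[LrgRecord, TruthTables]:
    """Seeded random single-transcript gene plus exhaustive oracle tables."""
    if spec.n_exons < 2:
        raise LrgError("need at least 2 exons to have an intron")
    rng = random.Random(spec.seed)

    exon_lens = [rng.randint(*spec.exon_length) for _ in range(spec.n_exons)]
    intron_lens = [rng.randint(*spec.intron_length)
                   for _ in range(spec.n_exons - 1)]
    total_exonic = sum(exon_lens)
    cds_len = total_exonic - spec.utr5_length - spec.utr3_length
    cds_len -= cds_len % 3
    if cds_len < 6:
        raise LrgError(
            f"spec unsatisfiable: exonic length {total_exonic} leaves CDS of "
            f"{cds_len} nt (< 6) after UTRs"
        )
    # (UTRs may span exon boundaries; the walks below do not care)

    # lay out exons with flanks
    exons: List[Tuple[int, int]] = []
    cursor = spec.flank_length + 1
    for i, length in enumerate(exon_lens):
        exons.append((cursor, cursor + length - 1))
        cursor += length
        if i < len(intron_lens):
            cursor += intron_lens[i]
    genome_len = cursor - 1 + spec.flank_length

    genomic = [rng.choice(_BASES) for _ in range(genome_len)]

    # genomic position of cds bounds via a naive exonic walk
    exonic_positions = [g for s, e in exons for g in range(s, e + 1)]
    cds_start_g = exonic_positions[spec.utr5_length]
    cds_end_g = exonic_positions[spec.utr5_length + cds_len - 1]
    cds_seq = _random_cds(rng, cds_len // 3)
    _paint_cds(genomic, exons, cds_start_g, cds_end_g, cds_seq)
    genomic_seq = "".join(genomic)

    record = build_record(
        f"LRG_{spec.lrg_number}",
        genomic_seq,
        [TranscriptSpec(exons, cds_start_g, cds_end_g)],
    )

    # assembly mapping: single diff-free span over the whole record
    if spec.assembly_strand == 1:
        span = MappingSpan(1, genome_len, spec.assembly_offset,
                           spec.assembly_offset + genome_len - 1, 1)
    else:
        span = MappingSpan(1, genome_len, spec.assembly_offset,
                           spec.assembly_offset + genome_len - 1, -1)
    mapping = AssemblyMapping(spec.assembly_name, spec.other_accession, [span])
    record.updatable.annotation_sets.append(
        AnnotationSet(source="lrgkit-fixture", modification_date="2010-04-15",
                      mappings=[mapping])
    )

    tables = _truth_tables(exons, spec.utr5_length, cds_len, span)
    return record, tables


def _truth_tables(exons: Sequence[Tuple[int, int]], utr5: int, cds_len: int,
                  span: MappingSpan) -> TruthTables:
    """Naive per-base walks; deliberately independent of coord_map."""
    tables = TruthTables()

    # exonic labels: walk every exonic base counting from the cDNA start
    exonic = [g for s, e in exons for g in range(s, e + 1)]
    for i, g in enumerate(exonic):  # i is 0-based cDNA index
        if i < utr5:
            tables.g_to_c[g] = CodingPosition(UTR5, i - utr5)
        elif i < utr5 + cds_len:
            tables.g_to_c[g] = CodingPosition(CDS, i - utr5 + 1)
        else:
            tables.g_to_c[g] = CodingPosition(UTR3, i - utr5 - cds_len + 1)

    # intronic labels: walk each intron base by base comparing distances
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        for g in range(e1 + 1, s2):
            k = g - e1
            m = s2 - g
            if k <= m:
                anchor = tables.g_to_c[e1]
                tables.g_to_c[g] = CodingPosition(anchor.region, anchor.anchor, k)
            else:
                anchor = tables.g_to_c[s2]
                tables.g_to_c[g] = CodingPosition(anchor.region, anchor.anchor, -m)

    # assembly correspondence: enumerate the span base by base
    other = (range(span.other_start, span.other_end + 1)
             if span.strand == 1
             else range(span.other_end, span.other_start - 1, -1))
    for g, o in zip(range(span.lrg_start, span.lrg_end + 1), other):
        tables.assembly[g] = (o, span.strand)

    # codon map
    n_residues = cds_len // 3 - 1
    for n in range(1, n_residues + 1):
        tables.codons[n] = (3 * n - 2, 3 * n - 1, 3 * n)
    return tables


# ---------------------------------------------------------------------------
# the engineered worked-example record
# ---------------------------------------------------------------------------

#: contig interval of the reverse-strand placement
CONTIG_START = 13535609
CONTIG_END = 13553152
CONTIG_ACCESSION = "NT_010783.15"


def make_col1a1_like() -> LrgRecord:
    """Engineered single-transcript record honouring the worked examples.

    Synthetic layout (not the real gene): 50 exons; exon 1 carries a 100 nt
    5' UTR then 69 coding nt; exons 2..35 are 69 nt coding; exon 36 is 36 nt
    coding, so its last base is c.2451; exons 37..49 are 69 nt coding; exon
    50 carries 102 coding nt (stop included) and a 200 nt 3' UTR.  All 49
    introns are 250 nt, flanks 772 nt, giving a genomic length equal to the
    contig interval 13535609..13553152 (17544 nt) mapped on the minus
    strand.  Codon 191 is GGC.
    """
    utr5, utr3 = 100, 200
    intron, flank = 250, 772
    exon_core = [69] * 35 + [36] + [69] * 13 + [102]  # coding nt per exon
    exon_lens = list(exon_core)
    exon_lens[0] += utr5
    exon_lens[-1] += utr3

    exons: List[Tuple[int, int]] = []
    cursor = flank + 1
    for i, length in enumerate(exon_lens):
        exons.append((cursor, cursor + length - 1))
        cursor += length + (intron if i < len(exon_lens) - 1 else 0)
    genome_len = cursor - 1 + flank
    expected = CONTIG_END - CONTIG_START + 1
    assert genome_len == expected, (genome_len, expected)

    cds_len = sum(exon_core)
    assert cds_len % 3 == 0

    rng = random.Random(20100415)
    genomic = [rng.choice(_BASES) for _ in range(genome_len)]
    cds_seq = _random_cds(rng, cds_len // 3)
    cds_seq = cds_seq[: 3 * 190] + "GGC" + cds_seq[3 * 191:]  # codon 191
    cds_seq = "ATG" + cds_seq[3:]  # conventional start codon
    cds_start_g = exons[0][0] + utr5
    cds_end_g = exons[-1][0] + 102 - 1
    _paint_cds(genomic, exons, cds_start_g, cds_end_g, cds_seq)

    record = build_record("LRG_1", "".join(genomic),
                          [TranscriptSpec(exons, cds_start_g, cds_end_g)])

    span = MappingSpan(1, genome_len, CONTIG_START, CONTIG_END, -1)
    mapping = AssemblyMapping("GRCh37", CONTIG_ACCESSION, [span])
    xrefs = [
        CrossReference("RefSeqGene", "NG_007400", 1, identical_to_lrg=True),
        CrossReference("RefSeq", "NM_000088", 3, identical_to_lrg=True),
        CrossReference("RefSeq", "NP_000079", 2, identical_to_lrg=True),
    ]
    # collagen-style legacy scheme: mature-chain numbering after the
    # N-propeptide, plus a split exon label
    legacy = LegacyMap(
        scheme_name="mature-chain",
        exon_labels={1: "1", 2: "2A", 3: "2B"},
        residue_shifts=[(24, len(record.fixed.transcripts[0].protein.sequence),
                         23)],
    )
    record.updatable.annotation_sets.append(
        AnnotationSet(
            source="lrgkit-fixture",
            modification_date="2010-04-15",
            mappings=[mapping],
            xrefs=xrefs,
            legacy_maps=[legacy],
            overlaps=[],
            notes=["synthetic record engineered for the printed worked "
                   "examples; not the real gene"],
        )
    )
    return record


def make_multi_transcript_fixture(seed: int = 0) -> LrgRecord:
    """Two transcripts sharing internal coding exons.

    t1 and t2 use different first (5' UTR) and last exons; t2 additionally
    skips a codon-aligned internal exon, so a shared-exon variant gets
    distinct c. anchors in the two transcripts while both still translate
    cleanly.
    """
    rng = random.Random(seed)

    # genomic layout: e1a (t1 UTR5), e1b (t2 UTR5), e2, e3 (skipped in t2),
    # e4, then alternative last exons e5a (t1) / e5b (t2, longer 3' UTR)
    gaps = [rng.randint(50, 150) for _ in range(7)]
    lens = {"e1a": 60, "e1b": 45, "e2": 120, "e3": 90, "e4": 150,
            "tail": 63, "utr3a": 80, "utr3b": 180}
    pos = {}
    cursor = gaps[0] + 1
    for name, extra in [("e1a", lens["e1a"]), ("e1b", lens["e1b"]),
                        ("e2", lens["e2"]), ("e3", lens["e3"]),
                        ("e4", lens["e4"]),
                        ("e5", lens["tail"] + lens["utr3b"])]:
        pos[name] = (cursor, cursor + extra - 1)
        cursor += extra + gaps.pop(0) if gaps else extra
    genome_len = cursor + 100

    e5_start = pos["e5"][0]
    e5a = (e5_start, e5_start + lens["tail"] + lens["utr3a"] - 1)
    e5b = (e5_start, e5_start + lens["tail"] + lens["utr3b"] - 1)

    genomic = [rng.choice(_BASES) for _ in range(genome_len)]
    cds_start = pos["e2"][0]
    cds_end = e5_start + lens["tail"] - 1
    t1_exons = [pos["e1a"], pos["e2"], pos["e3"], pos["e4"], e5a]
    t2_exons = [pos["e1b"], pos["e2"], pos["e4"], e5b]

    # paint t1's CDS with stop-free codons (e3 is codon-aligned: 120 % 3 == 0,
    # 90 % 3 == 0, so t2's CDS is t1's minus whole codons -> also stop-free)
    cds_len = lens["e2"] + lens["e3"] + lens["e4"] + lens["tail"]
    assert cds_len % 3 == 0 and lens["e2"] % 3 == 0 and lens["e3"] % 3 == 0
    cds_seq = _random_cds(rng, cds_len // 3)
    _paint_cds(genomic, t1_exons, cds_start, cds_end, cds_seq)
    # ensure t2's terminal codon is still a stop (it is: same tail bases)

    record = build_record(
        "LRG_902", "".join(genomic),
        [TranscriptSpec(t1_exons, cds_start, cds_end),
         TranscriptSpec(t2_exons, cds_start, cds_end)],
    )
    record.updatable.annotation_sets.append(
        AnnotationSet(source="lrgkit-fixture", modification_date="2010-04-15",
                      notes=["multi-transcript fixture: alternative first and "
                             "last exons, one skipped internal exon"])
    )
    return record
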