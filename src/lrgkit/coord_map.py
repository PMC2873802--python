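"""Coordinate algebra: g.<->c. with intron offsets and UTR numbering,
c.->p. codon arithmetic, strand-aware record<->assembly mapping, and legacy
exon/residue renumbering.

Conventions (documented once, applied everywhere):

* all coordinates 1-based, fully inclusive;
* coding (c.) positions anchor on the CDS: anchor 1 is the first base of the
  start codon, the stop codon occupies the last three CDS anchors; 5' UTR
  bases count backwards as -1, -2, ...; 3' UTR bases count forwards as *1,
  *2, ... from the base after the stop codon;
* intronic bases in the proximal half of an intron anchor to the upstream
  exon's last base with a "+k" offset, the distal half to the downstream
  exon's first base with "-k"; the middle base of an odd-length intron goes
  to the "+" side;
* positions outside the transcript span (5' of the first exon, 3' of the
  last) are refused rather than extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

from .core_model import AssemblyMapping, LegacyMap, MappingSpan, Transcript
from .errors import (
    NonCodingTranscriptError,
    OffsetConventionError,
    OutOfSpanError,
    UnmappablePositionError,
)

UTR5 = "UTR5"
CDS = "CDS"
UTR3 = "UTR3"


@dataclass(frozen=True)
class CodingPosition:
    """An HGVS-style c. position: region, anchor, optional intron offset."""

    region: str  # UTR5 | CDS | UTR3
    anchor: int  # CDS: 1..cds_len; UTR5: -1,-2,...; UTR3: 1,2,... ("*n")
    intron_offset: int = 0

    def __post_init__(self):
        if self.anchor == 0:
            raise ValueError("anchor 0 does not exist (no position between "
                             "c.-1 and c.1)")
        if self.region == UTR5 and self.anchor > 0:
            raise ValueError("UTR5 anchors are negative")
        if self.region in (CDS, UTR3) and self.anchor < 0:
            raise ValueError(f"{self.region} anchors are positive")

    def __str__(self) -> str:
        if self.region == UTR3:
            base = f"*{self.anchor}"
        else:
            base = str(self.anchor)
        if self.intron_offset > 0:
            return f"{base}+{self.intron_offset}"
        if self.intron_offset < 0:
            return f"{base}{self.intron_offset}"
        return base


@dataclass(frozen=True)
class MappedPosition:
    accession: str
    position: int
    strand: int


# ---------------------------------------------------------------------------
# transcript-internal helpers
# ---------------------------------------------------------------------------

def _require_cds(transcript: Transcript) -> None:
    if transcript.coding_region is None:
        raise NonCodingTranscriptError(
            f"transcript {transcript.name} has no coding region; coding "
            "coordinates are undefined (n. numbering is not supported)"
        )


def _g_to_cdna(transcript: Transcript, g_pos: int) -> Optional[int]:
    """cDNA position for an exonic genomic position, else None."""
    for exon in transcript.exons:
        if exon.lrg_start <= g_pos <= exon.lrg_end:
            return exon.cdna_start + (g_pos - exon.lrg_start)
    return None


def _cdna_to_g(transcript: Transcript, n: int) -> int:
    for exon in transcript.exons:
        if exon.cdna_start <= n <= exon.cdna_end:
            return exon.lrg_start + (n - exon.cdna_start)
    raise OutOfSpanError(
        f"cDNA position {n} outside 1..{len(transcript.cdna_sequence)}"
    )


def _cds_cdna_bounds(transcript: Transcript) -> Tuple[int, int]:
    cr = transcript.coding_region
    start = _g_to_cdna(transcript, cr.cds_start)
    end = _g_to_cdna(transcript, cr.cds_end)
    if start is None or end is None:
        raise OutOfSpanError("CDS bounds are not exonic")
    return start, end


def _cdna_to_coding(transcript: Transcript, n: int) -> CodingPosition:
    cds_start, cds_end = _cds_cdna_bounds(transcript)
    if n < cds_start:
        return CodingPosition(UTR5, n - cds_start)
    if n <= cds_end:
        return CodingPosition(CDS, n - cds_start + 1)
    return CodingPosition(UTR3, n - cds_end)


def _coding_to_cdna(transcript: Transcript, c: CodingPosition) -> int:
    cds_start, cds_end = _cds_cdna_bounds(transcript)
    if c.region == UTR5:
        n = cds_start + c.anchor
    elif c.region == CDS:
        n = cds_start + c.anchor - 1
        if n > cds_end:
            raise OutOfSpanError(
                f"CDS anchor {c.anchor} beyond CDS length {cds_end - cds_start + 1}"
            )
    else:
        n = cds_end + c.anchor
    if not (1 <= n <= len(transcript.cdna_sequence)):
        raise OutOfSpanError(
            f"position {c} resolves outside the transcript "
            f"(cDNA 1..{len(transcript.cdna_sequence)})"
        )
    return n


# ---------------------------------------------------------------------------
# g. <-> c.
# ---------------------------------------------------------------------------

def g_to_c(transcript: Transcript, g_pos: int) -> CodingPosition:
    """Label a genomic position within the transcript span in c. coordinates.

    Exonic positions get offset 0; intronic positions anchor to the nearest
    exon boundary under the midpoint convention described in the module
    docstring.
    """
    _require_cds(transcript)
    if not (transcript.span_start <= g_pos <= transcript.span_end):
        raise OutOfSpanError(
            f"position {g_pos} outside transcript {transcript.name} span "
            f"{transcript.span_start}..{transcript.span_end}"
        )
    n = _g_to_cdna(transcript, g_pos)
    if n is not None:
        return _cdna_to_coding(transcript, n)

    # intronic: find flanking exons
    for left, right in zip(transcript.exons, transcript.exons[1:]):
        if left.lrg_end < g_pos < right.lrg_start:
            k = g_pos - left.lrg_end          # distance past the donor
            m = right.lrg_start - g_pos       # distance before the acceptor
            if k <= m:  # ties (odd-length intron midpoint) go to "+"
                base = _cdna_to_coding(transcript, left.cdna_end)
                return CodingPosition(base.region, base.anchor, k)
            base = _cdna_to_coding(transcript, right.cdna_start)
            return CodingPosition(base.region, base.anchor, -m)
    raise OutOfSpanError(f"position {g_pos} not locatable in {transcript.name}")


def c_to_g(transcript: Transcript, c: CodingPosition) -> int:
    """Resolve a c. position to a genomic position; inverse of :func:`g_to_c`.

    Offsets that walk past the intron midpoint (into territory labelled from
    the other boundary) are refused to keep descriptions unambiguous.
    """
    _require_cds(transcript)
    n = _coding_to_cdna(transcript, c)
    g_anchor = _cdna_to_g(transcript, n)
    if c.intron_offset == 0:
        return g_anchor

    if c.intron_offset > 0:
        idx = _exon_index_with(transcript, lambda e: e.lrg_end == g_anchor)
        if idx is None or idx == len(transcript.exons) - 1:
            raise OffsetConventionError(
                f"'+' offset requires the anchor to be a donor-side exon "
                f"boundary; {c} anchors at genomic {g_anchor}"
            )
        intron_len = transcript.exons[idx + 1].lrg_start - g_anchor - 1
        k = c.intron_offset
        if k > intron_len:
            raise OutOfSpanError(
                f"offset +{k} exceeds intron length {intron_len}"
            )
        if k > (intron_len + 1) // 2:
            raise OffsetConventionError(
                f"offset +{k} crosses the midpoint of a {intron_len} nt "
                f"intron; that base is labelled from the downstream boundary"
            )
        return g_anchor + k

    idx = _exon_index_with(transcript, lambda e: e.lrg_start == g_anchor)
    if idx is None or idx == 0:
        raise OffsetConventionError(
            f"'-' offset requires the anchor to be an acceptor-side exon "
            f"boundary; {c} anchors at genomic {g_anchor}"
        )
    intron_len = g_anchor - transcript.exons[idx - 1].lrg_end - 1
    m = -c.intron_offset
    if m > intron_len:
        raise OutOfSpanError(f"offset -{m} exceeds intron length {intron_len}")
    if m > intron_len // 2:
        raise OffsetConventionError(
            f"offset -{m} crosses the midpoint of a {intron_len} nt intron; "
            f"that base is labelled from the upstream boundary"
        )
    return g_anchor - m


def _exon_index_with(transcript: Transcript, pred) -> Optional[int]:
    for i, exon in enumerate(transcript.exons):
        if pred(exon):
            return i
    return None


def c_to_p(c: CodingPosition) -> int:
    """Residue index of a CDS-exonic coding position: ``(anchor-1)//3 + 1``."""
    if c.region != CDS or c.intron_offset != 0:
        raise OutOfSpanError(
            f"position {c} has no protein residue (UTR or intronic)"
        )
    return (c.anchor - 1) // 3 + 1


# ---------------------------------------------------------------------------
# record <-> assembly mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Block:
    """A colinear gap-free run: lrg_start..lrg_end <-> other_start..other_end.

    On the minus strand the record's first base pairs with the target's
    last: ``lrg_start <-> other_end``.
    """

    lrg_start: int
    lrg_end: int
    other_start: int
    other_end: int
    strand: int


def _span_blocks(span: MappingSpan) -> list[_Block]:
    """Decompose a span into gap-free blocks; insertions break blocks."""
    inserts = [d for d in span.diffs if d.kind != "mismatch"]
    inserts.sort(key=lambda d: (d.lrg_start, d.other_start))
    blocks: list[_Block] = []
    l_cur = span.lrg_start
    if span.strand == 1:
        o_cur = span.other_start
        for d in inserts:
            l_before = (d.lrg_start - 1) if d.kind == "lrg_insertion" else d.lrg_start - 1
            run = l_before - l_cur + 1
            if run > 0:
                blocks.append(_Block(l_cur, l_before, o_cur, o_cur + run - 1, 1))
                l_cur += run
                o_cur += run
            if d.kind == "lrg_insertion":
                l_cur = d.lrg_end + 1
            else:
                o_cur = d.other_end + 1
        if l_cur <= span.lrg_end:
            run = span.lrg_end - l_cur + 1
            blocks.append(_Block(l_cur, span.lrg_end, o_cur, o_cur + run - 1, 1))
    else:
        o_cur = span.other_end  # minus strand walks the target downwards
        for d in inserts:
            l_before = (d.lrg_start - 1) if d.kind == "lrg_insertion" else d.lrg_start - 1
            run = l_before - l_cur + 1
            if run > 0:
                blocks.append(_Block(l_cur, l_before, o_cur - run + 1, o_cur, -1))
                l_cur += run
                o_cur -= run
            if d.kind == "lrg_insertion":
                l_cur = d.lrg_end + 1
            else:
                o_cur = d.other_start - 1
        if l_cur <= span.lrg_end:
            run = span.lrg_end - l_cur + 1
            blocks.append(_Block(l_cur, span.lrg_end, o_cur - run + 1, o_cur, -1))
    return blocks


def _flanks_for(blocks: list[_Block], lrg_pos: int) -> tuple:
    left = max((b.lrg_end for b in blocks if b.lrg_end < lrg_pos), default=None)
    right = min((b.lrg_start for b in blocks if b.lrg_start > lrg_pos), default=None)
    return (left, right)


def map_lrg_to_other(mapping: AssemblyMapping, lrg_pos: int) -> MappedPosition:
    """Project a record position onto the mapping's target sequence.

    Positions inside a record-side insertion are unmappable; the raised
    error carries the nearest mapped flanking positions.
    """
    for span in mapping.spans:
        if span.lrg_start <= lrg_pos <= span.lrg_end:
            blocks = _span_blocks(span)
            for b in blocks:
                if b.lrg_start <= lrg_pos <= b.lrg_end:
                    off = lrg_pos - b.lrg_start
                    pos = (b.other_start + off if b.strand == 1
                           else b.other_end - off)
                    return MappedPosition(mapping.other_accession, pos, b.strand)
            raise UnmappablePositionError(
                f"position {lrg_pos} lies inside a record-side insertion and "
                f"has no counterpart on {mapping.other_accession}",
                flanks=_flanks_for(blocks, lrg_pos),
            )
    covered = ", ".join(f"{s.lrg_start}..{s.lrg_end}" for s in mapping.spans)
    raise UnmappablePositionError(
        f"position {lrg_pos} not covered by any mapping span (covered: "
        f"{covered or 'none'})"
    )


def map_other_to_lrg(mapping: AssemblyMapping, accession: str, pos: int) -> int:
    """Inverse of :func:`map_lrg_to_other` on mapped bases."""
    if accession != mapping.other_accession:
        raise UnmappablePositionError(
            f"mapping targets {mapping.other_accession}, not {accession}"
        )
    for span in mapping.spans:
        lo, hi = min(span.other_start, span.other_end), max(span.other_start,
                                                            span.other_end)
        if lo <= pos <= hi:
            blocks = _span_blocks(span)
            for b in blocks:
                if b.other_start <= pos <= b.other_end:
                    off = (pos - b.other_start if b.strand == 1
                           else b.other_end - pos)
                    return b.lrg_start + off
            raise UnmappablePositionError(
                f"{accession}:{pos} lies inside a target-side insertion and "
                "has no record counterpart"
            )
    raise UnmappablePositionError(
        f"{accession}:{pos} not covered by any mapping span"
    )


# ---------------------------------------------------------------------------
# legacy numbering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LegacyLabel:
    label: str
    scheme: str
    systematic_fallback: bool = False


def legacy_exon_label(legacy: LegacyMap, exon_ordinal: int) -> LegacyLabel:
    """Legacy label for a systematic exon ordinal; falls back to the
    systematic number (flagged) when the scheme is silent."""
    if exon_ordinal in legacy.exon_labels:
        return LegacyLabel(legacy.exon_labels[exon_ordinal], legacy.scheme_name)
    return LegacyLabel(str(exon_ordinal), legacy.scheme_name,
                       systematic_fallback=True)


def legacy_residue_number(legacy: LegacyMap, residue: int) -> Tuple[int, str]:
    """Legacy residue number: ``systematic - shift`` for the covering range."""
    for start, end, shift in legacy.residue_shifts:
        if start <= residue <= end:
            return residue - shift, legacy.scheme_name
    ranges = ", ".join(f"{s}..{e}" for s, e, _ in legacy.residue_shifts)
    raise OutOfSpanError(
        f"residue {residue} outside all declared ranges of scheme "
        f"{legacy.scheme_name!r} ({ranges or 'none'})"
    )
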