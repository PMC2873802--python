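"""Domain types for two-layer locus reference records.

A record has an immutable *fixed* layer (genomic sequence, transcripts, exon
markup, CDS bounds, cDNA and protein sequences) and a date-stamped
*updatable* layer (assembly mappings, cross-references, legacy numbering
maps, overlap reports, notes).  Every coordinate in this package is 1-based
and fully inclusive.

Validation reports findings rather than raising; the fixed-layer digest is a
SHA-256 over a canonical JSON serialization of fixed-layer content only, so
any updatable-layer edit leaves it untouched.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from . import seq_ops
from .errors import InvalidRecordError

LRG_ID_RE = re.compile(r"^LRG_[1-9][0-9]*$")

DIGEST_ALGORITHM = "sha256"


# ---------------------------------------------------------------------------
# Fixed layer
# ---------------------------------------------------------------------------

@dataclass
class Exon:
    """One exon with markup in all three coordinate systems.

    ``lrg_*`` are positions on the record's genomic sequence, ``cdna_*`` on
    the transcript's spliced sequence, ``peptide_*`` the residue bounds the
    exon contributes to (absent for UTR-only exons).
    """

    lrg_start: int
    lrg_end: int
    cdna_start: int
    cdna_end: int
    peptide_start: Optional[int] = None
    peptide_end: Optional[int] = None

    @property
    def length(self) -> int:
        return self.lrg_end - self.lrg_start + 1


@dataclass
class CodingRegion:
    """Genomic bounds of the CDS: first base of the start codon through the
    last base of the stop codon."""

    cds_start: int
    cds_end: int


@dataclass
class ProteinProduct:
    name: str  # "p<k>" paired with transcript "t<k>"
    sequence: str  # one-letter codes, no terminal stop


@dataclass
class Transcript:
    name: str  # "t<k>"
    exons: List[Exon]
    cdna_sequence: str
    coding_region: Optional[CodingRegion] = None
    protein: Optional[ProteinProduct] = None

    @property
    def span_start(self) -> int:
        return self.exons[0].lrg_start

    @property
    def span_end(self) -> int:
        return self.exons[-1].lrg_end


@dataclass
class FixedAnnotation:
    sequence: str
    transcripts: List[Transcript] = field(default_factory=list)
    organism: str = "Homo sapiens"
    taxon_id: int = 9606


# ---------------------------------------------------------------------------
# Updatable layer
# ---------------------------------------------------------------------------

@dataclass
class SeqDiff:
    """One alignment difference inside a mapping span.

    ``kind`` is ``mismatch`` (equal-length intervals), ``lrg_insertion``
    (bases present only on the record side; the other interval is empty) or
    ``other_insertion`` (bases present only on the target side).  Empty
    intervals use the convention ``end == start - 1`` with ``start`` at the
    position the missing bases would occupy.
    """

    kind: str
    lrg_start: int
    lrg_end: int
    other_start: int
    other_end: int
    lrg_sequence: str = ""
    other_sequence: str = ""


@dataclass
class MappingSpan:
    lrg_start: int
    lrg_end: int
    other_start: int
    other_end: int
    strand: int  # +1 or -1
    diffs: List[SeqDiff] = field(default_factory=list)


@dataclass
class AssemblyMapping:
    assembly_name: str
    other_accession: str
    spans: List[MappingSpan] = field(default_factory=list)


@dataclass
class CrossReference:
    source_db: str
    accession: str
    version: Optional[int] = None
    identical_to_lrg: bool = False

    @property
    def versioned_accession(self) -> str:
        if self.version is None:
            return self.accession
        return f"{self.accession}.{self.version}"


@dataclass
class LegacyMap:
    """Legacy exon labels and residue renumbering for one published scheme.

    ``residue_shifts`` holds ``(start, end, shift)`` triples over systematic
    residue numbers; the legacy number is ``systematic - shift``.
    """

    scheme_name: str
    exon_labels: Dict[int, str] = field(default_factory=dict)
    residue_shifts: List[Tuple[int, int, int]] = field(default_factory=list)


@dataclass
class OverlapReport:
    identifier: str  # overlapping LRG id or gene symbol
    strand: int = 1


@dataclass
class AnnotationSet:
    source: str
    modification_date: str  # ISO 8601 date
    mappings: List[AssemblyMapping] = field(default_factory=list)
    xrefs: List[CrossReference] = field(default_factory=list)
    legacy_maps: List[LegacyMap] = field(default_factory=list)
    overlaps: List[OverlapReport] = field(default_factory=list)
    notes: List[str] = field(default_factory=list)
    #: serialized unknown XML elements, preserved verbatim on rewrite
    opaque: List[str] = field(default_factory=list)


@dataclass
class UpdatableAnnotation:
    annotation_sets: List[AnnotationSet] = field(default_factory=list)


@dataclass
class LrgRecord:
    lrg_id: str
    fixed: FixedAnnotation
    updatable: UpdatableAnnotation = field(default_factory=UpdatableAnnotation)

    def transcript(self, name: str) -> Transcript:
        for t in self.fixed.transcripts:
            if t.name == name:
                return t
        raise InvalidRecordError(
            f"{self.lrg_id} has no transcript {name!r}; available: "
            + ", ".join(t.name for t in self.fixed.transcripts)
        )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class Finding:
    severity: str  # "error" | "warning"
    code: str
    message: str
    location: str


def _finding(findings, severity, code, message, location):
    findings.append(Finding(severity, code, message, location))


ISO_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")
LEGAL_ID_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_.-]*$")


def validate_record(record: LrgRecord) -> List[Finding]:
    """Check every structural invariant; returns findings, never raises.

    An empty list means the record is internally consistent: cDNA sequences
    equal the spliced exon concatenation, proteins equal the translated CDS,
    exon markup is coherent across the three coordinate systems, and every
    updatable-layer item is well-formed.
    """
    findings: List[Finding] = []
    fx = record.fixed

    if not LRG_ID_RE.match(record.lrg_id):
        _finding(findings, "error", "ID_FORMAT",
                 f"id {record.lrg_id!r} does not match LRG_<positive integer>",
                 "lrg_id")

    _validate_fixed(record.lrg_id, fx, findings)
    _validate_updatable(record, findings)
    return findings


def _validate_fixed(lrg_id: str, fx: FixedAnnotation, findings: List[Finding]) -> None:
    loc = "fixed"
    seq = fx.sequence
    if len(seq) < 1:
        _finding(findings, "error", "EMPTY_SEQUENCE", "genomic sequence is empty", loc)
        return
    bad = set(seq) - seq_ops.DNA_ALPHABET
    if bad:
        _finding(findings, "error", "SEQ_ALPHABET",
                 f"genomic sequence contains foreign characters {sorted(bad)}", loc)
        return
    if "N" in seq:
        _finding(findings, "warning", "SEQ_AMBIGUOUS",
                 f"genomic sequence contains {seq.count('N')} N bases", loc)

    if not fx.transcripts:
        _finding(findings, "warning", "NO_TRANSCRIPTS",
                 "record has no transcripts (regulatory-region record?)", loc)

    names = [t.name for t in fx.transcripts]
    expected = [f"t{i}" for i in range(1, len(names) + 1)]
    if names != expected:
        _finding(findings, "error", "TRANSCRIPT_NAMES",
                 f"transcript names {names} are not consecutive from t1", loc)

    for t in fx.transcripts:
        _validate_transcript(seq, t, findings)


def _validate_transcript(seq: str, t: Transcript, findings: List[Finding]) -> None:
    loc = f"fixed/{t.name}"
    if not t.exons:
        _finding(findings, "error", "NO_EXONS", "transcript has no exons", loc)
        return

    prev_end = 0
    prev_cdna_end = 0
    ok_structure = True
    for i, exon in enumerate(t.exons, start=1):
        eloc = f"{loc}/exon{i}"
        if exon.lrg_end < exon.lrg_start:
            _finding(findings, "error", "EXON_BOUNDS",
                     f"lrg_end {exon.lrg_end} < lrg_start {exon.lrg_start}", eloc)
            ok_structure = False
            continue
        if exon.lrg_start < 1 or exon.lrg_end > len(seq):
            _finding(findings, "error", "EXON_BOUNDS",
                     f"exon {exon.lrg_start}..{exon.lrg_end} outside sequence "
                     f"1..{len(seq)}", eloc)
            ok_structure = False
        if exon.lrg_start <= prev_end:
            _finding(findings, "error", "EXON_ORDER",
                     f"exon start {exon.lrg_start} does not follow previous "
                     f"exon end {prev_end}", eloc)
            ok_structure = False
        if (exon.cdna_end - exon.cdna_start) != (exon.lrg_end - exon.lrg_start):
            _finding(findings, "error", "EXON_LENGTH_MISMATCH",
                     f"cdna interval {exon.cdna_start}..{exon.cdna_end} length "
                     f"differs from lrg interval", eloc)
            ok_structure = False
        if exon.cdna_start != prev_cdna_end + 1:
            _finding(findings, "error", "CDNA_GAP",
                     f"cdna_start {exon.cdna_start} does not abut previous "
                     f"cdna_end {prev_cdna_end}", eloc)
            ok_structure = False
        prev_end = exon.lrg_end
        prev_cdna_end = exon.cdna_end

    if ok_structure:
        spliced = seq_ops.splice(seq, t.exons)
        if spliced != t.cdna_sequence:
            _finding(findings, "error", "CDNA_MISMATCH",
                     "stored cdna_sequence differs from spliced exon "
                     "concatenation", loc)

    if (t.coding_region is None) != (t.protein is None):
        _finding(findings, "error", "CODING_PROTEIN_PAIRING",
                 "coding_region and protein must be present together", loc)
        return
    if t.coding_region is None:
        return

    cr = t.coding_region
    cloc = f"{loc}/coding_region"
    if not ok_structure:
        return
    in_exon_start = any(e.lrg_start <= cr.cds_start <= e.lrg_end for e in t.exons)
    in_exon_end = any(e.lrg_start <= cr.cds_end <= e.lrg_end for e in t.exons)
    if not (in_exon_start and in_exon_end):
        _finding(findings, "error", "CDS_OUTSIDE_EXON",
                 f"CDS bounds {cr.cds_start}..{cr.cds_end} not inside exons", cloc)
        return
    cds = seq_ops.extract_cds(seq, t.exons, cr.cds_start, cr.cds_end)
    if len(cds) % 3 != 0:
        _finding(findings, "error", "CDS_FRAME",
                 f"exonic CDS length {len(cds)} is not a multiple of 3", cloc)
        return
    if "N" in cds:
        _finding(findings, "error", "CDS_CONTAINS_N",
                 f"CDS contains N at CDS position {cds.index('N') + 1}", cloc)
        return
    try:
        protein = seq_ops.translate(cds)
    except Exception as exc:  # malformed CDS -> finding, not exception
        _finding(findings, "error", "CDS_TRANSLATION", str(exc), cloc)
        return

    expected_pname = "p" + t.name[1:]
    if t.protein.name != expected_pname:
        _finding(findings, "error", "PROTEIN_NAME",
                 f"protein name {t.protein.name!r} should be {expected_pname!r}",
                 f"{loc}/protein")
    if t.protein.sequence != protein:
        _finding(findings, "error", "PROTEIN_MISMATCH",
                 "stored protein differs from translated CDS", f"{loc}/protein")

    # peptide markup coherence
    plen = len(protein)
    for i, exon in enumerate(t.exons, start=1):
        if exon.peptide_start is None:
            continue
        if exon.peptide_end is None or not (
            1 <= exon.peptide_start <= exon.peptide_end <= plen
        ):
            _finding(findings, "error", "PEPTIDE_BOUNDS",
                     f"peptide bounds {exon.peptide_start}..{exon.peptide_end} "
                     f"outside protein 1..{plen}", f"{loc}/exon{i}")


def _validate_updatable(record: LrgRecord, findings: List[Finding]) -> None:
    seq_len = len(record.fixed.sequence)
    for si, aset in enumerate(record.updatable.annotation_sets, start=1):
        loc = f"updatable/set{si}"
        if not aset.modification_date or not ISO_DATE_RE.match(aset.modification_date):
            _finding(findings, "error", "MISSING_DATE",
                     f"annotation set has no ISO 8601 modification_date "
                     f"(got {aset.modification_date!r})", loc)
        for mi, mapping in enumerate(aset.mappings, start=1):
            _validate_mapping(mapping, seq_len, findings, f"{loc}/mapping{mi}")
        for xref in aset.xrefs:
            if xref.identical_to_lrg and xref.version is None:
                _finding(findings, "error", "XREF_VERSION",
                         f"identical_to_lrg xref {xref.accession} must be "
                         "versioned", loc)
        for lm in aset.legacy_maps:
            _validate_legacy_map(record, lm, findings, f"{loc}/legacy:{lm.scheme_name}")
        for ov in aset.overlaps:
            if not LEGAL_ID_RE.match(ov.identifier) or ov.strand not in (1, -1):
                _finding(findings, "error", "OVERLAP_ID",
                         f"malformed overlap report {ov.identifier!r} "
                         f"strand {ov.strand}", loc)


def _validate_mapping(mapping: AssemblyMapping, seq_len: int,
                      findings: List[Finding], loc: str) -> None:
    prev_end = 0
    for si, span in enumerate(sorted(mapping.spans, key=lambda s: s.lrg_start),
                              start=1):
        sloc = f"{loc}/span{si}"
        if span.strand not in (1, -1):
            _finding(findings, "error", "SPAN_STRAND",
                     f"strand {span.strand} not in {{+1, -1}}", sloc)
        if span.lrg_start <= prev_end:
            _finding(findings, "error", "SPAN_OVERLAP",
                     f"span starting at {span.lrg_start} overlaps previous span",
                     sloc)
        if span.lrg_end > seq_len or span.lrg_start < 1:
            _finding(findings, "error", "SPAN_BOUNDS",
                     f"span {span.lrg_start}..{span.lrg_end} outside sequence",
                     sloc)
        lrg_len = span.lrg_end - span.lrg_start + 1
        other_len = span.other_end - span.other_start + 1
        shift = 0
        for diff in span.diffs:
            dl = diff.lrg_end - diff.lrg_start + 1
            do = diff.other_end - diff.other_start + 1
            if diff.kind == "mismatch":
                if dl != do or dl < 1:
                    _finding(findings, "error", "DIFF_SHAPE",
                             "mismatch diff intervals must be equal and "
                             "non-empty", sloc)
            elif diff.kind == "lrg_insertion":
                if do != 0 or dl < 1:
                    _finding(findings, "error", "DIFF_SHAPE",
                             "lrg_insertion must have empty other interval", sloc)
                shift -= dl
            elif diff.kind == "other_insertion":
                if dl != 0 or do < 1:
                    _finding(findings, "error", "DIFF_SHAPE",
                             "other_insertion must have empty lrg interval", sloc)
                shift += do
            else:
                _finding(findings, "error", "DIFF_SHAPE",
                         f"unknown diff kind {diff.kind!r}", sloc)
        if other_len != lrg_len + shift:
            _finding(findings, "error", "SPAN_LENGTH",
                     f"interval lengths differ after diffs: lrg {lrg_len} + "
                     f"shift {shift} != other {other_len}", sloc)
        prev_end = max(prev_end, span.lrg_end)


def _validate_legacy_map(record: LrgRecord, lm: LegacyMap,
                         findings: List[Finding], loc: str) -> None:
    max_exons = max((len(t.exons) for t in record.fixed.transcripts), default=0)
    for ordinal in lm.exon_labels:
        if not (1 <= ordinal <= max_exons):
            _finding(findings, "error", "LEGACY_EXON_ORDINAL",
                     f"exon ordinal {ordinal} does not exist (max {max_exons})",
                     loc)
    ranges = sorted((s, e) for s, e, _ in lm.residue_shifts)
    for (s1, e1), (s2, _e2) in zip(ranges, ranges[1:]):
        if s2 <= e1:
            _finding(findings, "error", "LEGACY_RANGE_OVERLAP",
                     f"residue ranges {s1}..{e1} and starting {s2} overlap", loc)


# ---------------------------------------------------------------------------
# Fixed-layer digest & new-ID policy
# ---------------------------------------------------------------------------

def _canonical_fixed(fx: FixedAnnotation) -> dict:
    return {
        "organism": fx.organism,
        "taxon_id": fx.taxon_id,
        "sequence": fx.sequence,
        "transcripts": [
            {
                "name": t.name,
                "cdna_sequence": t.cdna_sequence,
                "exons": [
                    [e.lrg_start, e.lrg_end, e.cdna_start, e.cdna_end,
                     e.peptide_start, e.peptide_end]
                    for e in t.exons
                ],
                "coding_region": (
                    None if t.coding_region is None
                    else [t.coding_region.cds_start, t.coding_region.cds_end]
                ),
                "protein": (
                    None if t.protein is None
                    else {"name": t.protein.name, "sequence": t.protein.sequence}
                ),
            }
            for t in fx.transcripts
        ],
    }


def fixed_layer_digest(record: LrgRecord) -> str:
    """SHA-256 hex digest of the canonical fixed-layer serialization.

    Two records share a digest iff their fixed layers are canonically equal;
    updatable-layer content never participates.  Raises on the first fixed-
    layer invariant violation.
    """
    errors = [f for f in validate_record(record)
              if f.severity == "error" and f.location.startswith("fixed")]
    if errors:
        first = errors[0]
        raise InvalidRecordError(
            f"invalid fixed layer: [{first.code}] {first.message} "
            f"at {first.location}"
        )
    payload = json.dumps(_canonical_fixed(record.fixed),
                         sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()


@dataclass
class PolicyDecision:
    decision: str  # "allowed" | "requires_new_id"
    reason: str


def check_new_id_policy(existing: LrgRecord, proposed: LrgRecord) -> PolicyDecision:
    """Decide whether ``proposed`` may replace ``existing`` under the same id.

    Any fixed-layer change (sequence, exon markup, CDS bounds, transcripts)
    requires minting a new record id; updatable-layer changes are allowed.
    """
    if existing.lrg_id != proposed.lrg_id:
        raise InvalidRecordError(
            f"policy applies within one id: {existing.lrg_id} != {proposed.lrg_id}"
        )
    d_old = fixed_layer_digest(existing)
    d_new = fixed_layer_digest(proposed)
    if d_old == d_new:
        return PolicyDecision("allowed", "fixed layer unchanged; only "
                              "updatable-layer items differ")
    reason = _describe_fixed_change(existing.fixed, proposed.fixed)
    return PolicyDecision("requires_new_id", reason)


def _describe_fixed_change(old: FixedAnnotation, new: FixedAnnotation) -> str:
    if old.sequence != new.sequence:
        return (f"genomic sequence changed (length {len(old.sequence)} -> "
                f"{len(new.sequence)})")
    old_t = {t.name: t for t in old.transcripts}
    new_t = {t.name: t for t in new.transcripts}
    if set(old_t) != set(new_t):
        return f"transcript set changed: {sorted(old_t)} -> {sorted(new_t)}"
    for name, t_old in old_t.items():
        t_new = new_t[name]
        if [(e.lrg_start, e.lrg_end) for e in t_old.exons] != [
            (e.lrg_start, e.lrg_end) for e in t_new.exons
        ]:
            return f"exon markup of {name} changed"
        if t_old.coding_region != t_new.coding_region:
            return f"CDS bounds of {name} changed"
        if t_old.cdna_sequence != t_new.cdna_sequence:
            return f"cDNA sequence of {name} changed"
        if t_old.protein != t_new.protein:
            return f"protein of {name} changed"
    return "fixed-layer content changed"
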