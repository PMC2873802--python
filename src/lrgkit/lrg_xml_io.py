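"""Read/write the record XML dialect, structural schema validation, text
rendering, and FASTA/BED12/GFF3 export.

The dialect (version-controlled here as ``SCHEMA_VERSION``) mirrors the
two-section layout: a ``fixed_annotation`` element holding the genomic
sequence and per-transcript cDNA, protein and exon markup in all three
coordinate systems, and an ``updatable_annotation`` element holding dated
annotation sets.  Unknown elements inside an annotation set are preserved
verbatim and re-emitted on write; unknown elements in the fixed section are
errors.

Everything internal is 1-based inclusive; the only place 0-based half-open
coordinates appear is BED export, where the conversion happens at the last
moment.
"""

from __future__ import annotations

import copy
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import List, Optional, Tuple

from . import coord_map, seq_ops
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
    OverlapReport,
    ProteinProduct,
    SeqDiff,
    Transcript,
    UpdatableAnnotation,
    validate_record,
)
from .errors import InvalidRecordError, LrgError, UnmappablePositionError

SCHEMA_VERSION = "1.0"

_FIXED_CHILDREN = {"id", "organism", "sequence", "transcript"}
_KNOWN_SET_CHILDREN = {"source", "modification_date", "mapping", "xref",
                       "legacy_map", "overlap", "note"}


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_lrg(record: LrgRecord) -> str:
    """Serialize a record to the XML dialect; deterministic byte-for-byte.

    Refuses records with validation errors (warnings are tolerated).
    """
    errors = [f for f in validate_record(record) if f.severity == "error"]
    if errors:
        listing = "; ".join(f"[{f.code}] {f.message} @ {f.location}"
                            for f in errors[:5])
        raise InvalidRecordError(f"refusing to write invalid record: {listing}")

    root = ET.Element("lrg", schema_version=SCHEMA_VERSION)
    fixed = ET.SubElement(root, "fixed_annotation")
    ET.SubElement(fixed, "id").text = record.lrg_id
    org = ET.SubElement(fixed, "organism", taxon=str(record.fixed.taxon_id))
    org.text = record.fixed.organism
    ET.SubElement(fixed, "sequence").text = record.fixed.sequence
    for t in record.fixed.transcripts:
        fixed.append(_transcript_element(t))

    upd = ET.SubElement(root, "updatable_annotation")
    for aset in record.updatable.annotation_sets:
        upd.append(_annotation_set_element(aset))

    ET.indent(root, space="  ")
    return ET.tostring(root, encoding="unicode", xml_declaration=True) + "\n"


def _transcript_element(t: Transcript) -> ET.Element:
    el = ET.Element("transcript", name=t.name)
    cdna = ET.SubElement(el, "cdna")
    ET.SubElement(cdna, "sequence").text = t.cdna_sequence
    if t.coding_region is not None:
        cr = ET.SubElement(el, "coding_region",
                           start=str(t.coding_region.cds_start),
                           end=str(t.coding_region.cds_end))
        tr = ET.SubElement(cr, "translation", name=t.protein.name)
        ET.SubElement(tr, "sequence").text = t.protein.sequence
    for i, exon in enumerate(t.exons, start=1):
        ex = ET.SubElement(el, "exon", label=str(i))
        ET.SubElement(ex, "lrg_coords", start=str(exon.lrg_start),
                      end=str(exon.lrg_end))
        ET.SubElement(ex, "cdna_coords", start=str(exon.cdna_start),
                      end=str(exon.cdna_end))
        if exon.peptide_start is not None:
            ET.SubElement(ex, "peptide_coords", start=str(exon.peptide_start),
                          end=str(exon.peptide_end))
    return el


def _annotation_set_element(aset: AnnotationSet) -> ET.Element:
    el = ET.Element("annotation_set")
    ET.SubElement(el, "source").text = aset.source
    ET.SubElement(el, "modification_date").text = aset.modification_date
    for mapping in aset.mappings:
        mel = ET.SubElement(el, "mapping", assembly=mapping.assembly_name,
                            other_accession=mapping.other_accession)
        for span in mapping.spans:
            sel = ET.SubElement(
                mel, "mapping_span",
                lrg_start=str(span.lrg_start), lrg_end=str(span.lrg_end),
                other_start=str(span.other_start),
                other_end=str(span.other_end), strand=str(span.strand))
            for d in span.diffs:
                ET.SubElement(
                    sel, "diff", type=d.kind,
                    lrg_start=str(d.lrg_start), lrg_end=str(d.lrg_end),
                    other_start=str(d.other_start),
                    other_end=str(d.other_end),
                    lrg_sequence=d.lrg_sequence,
                    other_sequence=d.other_sequence)
    for xref in aset.xrefs:
        attrs = {"source": xref.source_db, "accession": xref.accession,
                 "identical_to_lrg": "true" if xref.identical_to_lrg else "false"}
        if xref.version is not None:
            attrs["version"] = str(xref.version)
        ET.SubElement(el, "xref", **attrs)
    for lm in aset.legacy_maps:
        lel = ET.SubElement(el, "legacy_map", scheme=lm.scheme_name)
        for ordinal in sorted(lm.exon_labels):
            ET.SubElement(lel, "exon_label", ordinal=str(ordinal),
                          label=lm.exon_labels[ordinal])
        for start, end, shift in lm.residue_shifts:
            ET.SubElement(lel, "residue_shift", start=str(start),
                          end=str(end), shift=str(shift))
    for ov in aset.overlaps:
        ET.SubElement(el, "overlap", id=ov.identifier, strand=str(ov.strand))
    for note in aset.notes:
        ET.SubElement(el, "note").text = note
    for raw in aset.opaque:
        el.append(ET.fromstring(raw))
    return el


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_lrg(xml_text: str) -> LrgRecord:
    """Parse the XML dialect back into a record.

    Unknown elements inside an annotation set are preserved as opaque
    content; unknown elements in the fixed section raise.
    """
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError as exc:
        raise LrgError(f"XML syntax error: {exc}") from exc
    if root.tag != "lrg":
        raise LrgError(f"root element is {root.tag!r}, expected 'lrg'")

    fixed_el = root.find("fixed_annotation")
    if fixed_el is None:
        raise LrgError("missing element at lrg/fixed_annotation")
    for child in fixed_el:
        if child.tag not in _FIXED_CHILDREN:
            raise LrgError(
                f"unknown fixed-layer element lrg/fixed_annotation/{child.tag}")

    lrg_id = _required_text(fixed_el, "id", "lrg/fixed_annotation")
    seq = _required_text(fixed_el, "sequence", "lrg/fixed_annotation")
    org_el = fixed_el.find("organism")
    organism = org_el.text if org_el is not None and org_el.text else "Homo sapiens"
    taxon_id = int(org_el.get("taxon", "9606")) if org_el is not None else 9606

    transcripts = [_parse_transcript(el) for el in fixed_el.findall("transcript")]
    fixed = FixedAnnotation(sequence=seq, transcripts=transcripts,
                            organism=organism, taxon_id=taxon_id)

    updatable = UpdatableAnnotation()
    upd_el = root.find("updatable_annotation")
    if upd_el is not None:
        for set_el in upd_el.findall("annotation_set"):
            updatable.annotation_sets.append(_parse_annotation_set(set_el))

    return LrgRecord(lrg_id=lrg_id, fixed=fixed, updatable=updatable)


def _required_text(parent: ET.Element, tag: str, path: str) -> str:
    el = parent.find(tag)
    if el is None or el.text is None:
        raise LrgError(f"missing element at {path}/{tag}")
    return el.text.strip()


def _parse_transcript(el: ET.Element) -> Transcript:
    name = el.get("name")
    if not name:
        raise LrgError("transcript without name attribute")
    cdna_el = el.find("cdna")
    if cdna_el is None:
        raise LrgError(f"missing element at transcript[{name}]/cdna")
    cdna = _required_text(cdna_el, "sequence", f"transcript[{name}]/cdna")
    coding_region = None
    protein = None
    cr_el = el.find("coding_region")
    if cr_el is not None:
        coding_region = CodingRegion(int(cr_el.get("start")),
                                     int(cr_el.get("end")))
        tr_el = cr_el.find("translation")
        if tr_el is None:
            raise LrgError(f"coding_region of {name} lacks translation")
        protein = ProteinProduct(
            name=tr_el.get("name", "p" + name[1:]),
            sequence=_required_text(tr_el, "sequence",
                                    f"transcript[{name}]/translation"),
        )
    exons = []
    for ex_el in el.findall("exon"):
        lrg = ex_el.find("lrg_coords")
        cd = ex_el.find("cdna_coords")
        if lrg is None or cd is None:
            raise LrgError(f"exon of {name} lacks lrg_coords/cdna_coords")
        pep = ex_el.find("peptide_coords")
        exons.append(Exon(
            int(lrg.get("start")), int(lrg.get("end")),
            int(cd.get("start")), int(cd.get("end")),
            int(pep.get("start")) if pep is not None else None,
            int(pep.get("end")) if pep is not None else None,
        ))
    return Transcript(name=name, exons=exons, cdna_sequence=cdna,
                      coding_region=coding_region, protein=protein)


def _parse_annotation_set(el: ET.Element) -> AnnotationSet:
    aset = AnnotationSet(
        source=_required_text(el, "source", "annotation_set"),
        modification_date=_required_text(el, "modification_date",
                                         "annotation_set"),
    )
    for child in el:
        if child.tag in ("source", "modification_date"):
            continue
        if child.tag == "mapping":
            mapping = AssemblyMapping(child.get("assembly", ""),
                                      child.get("other_accession", ""))
            for sp in child.findall("mapping_span"):
                span = MappingSpan(
                    int(sp.get("lrg_start")), int(sp.get("lrg_end")),
                    int(sp.get("other_start")), int(sp.get("other_end")),
                    int(sp.get("strand")))
                for d in sp.findall("diff"):
                    span.diffs.append(SeqDiff(
                        d.get("type"),
                        int(d.get("lrg_start")), int(d.get("lrg_end")),
                        int(d.get("other_start")), int(d.get("other_end")),
                        d.get("lrg_sequence", ""), d.get("other_sequence", "")))
                mapping.spans.append(span)
            aset.mappings.append(mapping)
        elif child.tag == "xref":
            version = child.get("version")
            aset.xrefs.append(CrossReference(
                child.get("source", ""), child.get("accession", ""),
                int(version) if version is not None else None,
                child.get("identical_to_lrg") == "true"))
        elif child.tag == "legacy_map":
            lm = LegacyMap(scheme_name=child.get("scheme", ""))
            for lab in child.findall("exon_label"):
                lm.exon_labels[int(lab.get("ordinal"))] = lab.get("label", "")
            for rs in child.findall("residue_shift"):
                lm.residue_shifts.append((int(rs.get("start")),
                                          int(rs.get("end")),
                                          int(rs.get("shift"))))
            aset.legacy_maps.append(lm)
        elif child.tag == "overlap":
            aset.overlaps.append(OverlapReport(child.get("id", ""),
                                               int(child.get("strand", "1"))))
        elif child.tag == "note":
            aset.notes.append(child.text or "")
        else:
            # forward compatibility: keep the element verbatim
            raw = copy.deepcopy(child)
            raw.tail = None
            aset.opaque.append(ET.tostring(raw, encoding="unicode"))
    return aset


# ---------------------------------------------------------------------------
# structural schema validation
# ---------------------------------------------------------------------------

@dataclass
class SchemaReport:
    valid: bool
    violations: List[Tuple[str, str]]


def validate_xml(xml_text: str) -> SchemaReport:
    """Check a document against the shipped dialect; report, never raise."""
    violations: List[Tuple[str, str]] = []
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError as exc:
        return SchemaReport(False, [("/", f"XML syntax error: {exc}")])

    if root.tag != "lrg":
        violations.append(("/", f"root element {root.tag!r} != 'lrg'"))
        return SchemaReport(False, violations)
    if root.get("schema_version") is None:
        violations.append(("/lrg", "missing schema_version attribute"))

    fixed = root.find("fixed_annotation")
    if fixed is None:
        violations.append(("/lrg", "missing fixed_annotation"))
    else:
        base = "/lrg/fixed_annotation"
        for tag in ("id", "sequence"):
            el = fixed.find(tag)
            if el is None or not (el.text or "").strip():
                violations.append((base, f"missing or empty <{tag}>"))
        for child in fixed:
            if child.tag not in _FIXED_CHILDREN:
                violations.append((f"{base}/{child.tag}",
                                   "unknown fixed-layer element"))
        for t_el in fixed.findall("transcript"):
            tname = t_el.get("name", "?")
            tbase = f"{base}/transcript[{tname}]"
            if not t_el.get("name"):
                violations.append((tbase, "transcript lacks name attribute"))
            if t_el.find("cdna/sequence") is None:
                violations.append((tbase, "missing cdna/sequence"))
            for i, ex_el in enumerate(t_el.findall("exon"), start=1):
                ebase = f"{tbase}/exon[{i}]"
                for coords in ("lrg_coords", "cdna_coords"):
                    c_el = ex_el.find(coords)
                    if c_el is None:
                        violations.append((ebase, f"missing {coords}"))
                        continue
                    start, end = _int_attrs(c_el, ("start", "end"),
                                            violations, f"{ebase}/{coords}")
                    if start is not None and end is not None and end < start:
                        violations.append((f"{ebase}/{coords}",
                                           f"end {end} < start {start}"))
            cr_el = t_el.find("coding_region")
            if cr_el is not None:
                _int_attrs(cr_el, ("start", "end"), violations,
                           f"{tbase}/coding_region")
                if cr_el.find("translation/sequence") is None:
                    violations.append((f"{tbase}/coding_region",
                                       "missing translation/sequence"))

    upd = root.find("updatable_annotation")
    if upd is not None:
        for i, set_el in enumerate(upd.findall("annotation_set"), start=1):
            sbase = f"/lrg/updatable_annotation/annotation_set[{i}]"
            for tag in ("source", "modification_date"):
                el = set_el.find(tag)
                if el is None or not (el.text or "").strip():
                    violations.append((sbase, f"missing or empty <{tag}>"))
            for sp in set_el.iter("mapping_span"):
                _int_attrs(sp, ("lrg_start", "lrg_end", "other_start",
                                "other_end", "strand"),
                           violations, f"{sbase}/mapping_span")

    return SchemaReport(not violations, violations)


def _int_attrs(el, names, violations, path):
    values = []
    for name in names:
        raw = el.get(name)
        try:
            values.append(int(raw))
        except (TypeError, ValueError):
            violations.append((path, f"attribute {name}={raw!r} is not an "
                               "integer"))
            values.append(None)
    return values if len(values) != 2 else tuple(values)


# ---------------------------------------------------------------------------
# text rendering
# ---------------------------------------------------------------------------

def render_text(record: LrgRecord) -> str:
    """Deterministic plain-text summary of a record."""
    lines = [
        f"Record: {record.lrg_id}",
        f"Organism: {record.fixed.organism} (taxon {record.fixed.taxon_id})",
        f"Genomic sequence: {len(record.fixed.sequence)} nt",
        f"Transcripts: {len(record.fixed.transcripts)}",
    ]
    for t in record.fixed.transcripts:
        lines.append("")
        lines.append(f"Transcript {t.name}: {len(t.exons)} exons, "
                     f"cDNA {len(t.cdna_sequence)} nt")
        if t.coding_region:
            lines.append(f"  CDS: {t.coding_region.cds_start}.."
                         f"{t.coding_region.cds_end}  protein {t.protein.name} "
                         f"({len(t.protein.sequence)} aa)")
        lines.append("  exon      lrg_start   lrg_end  cdna_start  cdna_end "
                     " pep_start   pep_end")
        for i, e in enumerate(t.exons, start=1):
            pep_s = e.peptide_start if e.peptide_start is not None else "-"
            pep_e = e.peptide_end if e.peptide_end is not None else "-"
            lines.append(f"  {i:>4}  {e.lrg_start:>11}  {e.lrg_end:>8}  "
                         f"{e.cdna_start:>10}  {e.cdna_end:>8}  "
                         f"{str(pep_s):>9}  {str(pep_e):>8}")
    for aset in record.updatable.annotation_sets:
        lines.append("")
        lines.append(f"Annotation set ({aset.source}, "
                     f"{aset.modification_date})")
        for m in aset.mappings:
            for s in m.spans:
                strand = "+" if s.strand == 1 else "-"
                lines.append(f"  mapping {m.assembly_name} "
                             f"{m.other_accession}: lrg {s.lrg_start}.."
                             f"{s.lrg_end} -> {s.other_start}..{s.other_end} "
                             f"strand {strand} ({len(s.diffs)} diffs)")
        for x in aset.xrefs:
            flag = " identical" if x.identical_to_lrg else ""
            lines.append(f"  xref {x.source_db}:{x.versioned_accession}{flag}")
        for lm in aset.legacy_maps:
            lines.append(f"  legacy scheme {lm.scheme_name}: "
                         f"{len(lm.exon_labels)} exon labels, "
                         f"{len(lm.residue_shifts)} residue ranges")
        for ov in aset.overlaps:
            strand = "+" if ov.strand == 1 else "-"
            lines.append(f"  overlap {ov.identifier} strand {strand}")
        for note in aset.notes:
            lines.append(f"  note: {note}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i:i + width] for i in range(0, len(seq), width))


def export_fasta(record: LrgRecord, what: str = "genomic",
                 transcript: Optional[str] = None) -> str:
    """FASTA export of the genomic, cDNA or protein sequence (60 columns)."""
    if what == "genomic":
        return f">{record.lrg_id}\n{_wrap(record.fixed.sequence)}\n"
    if transcript is None:
        raise LrgError(f"--transcript required for {what} export")
    t = record.transcript(transcript)
    if what == "cdna":
        return f">{record.lrg_id}{t.name}\n{_wrap(t.cdna_sequence)}\n"
    if what == "protein":
        if t.protein is None:
            raise LrgError(f"transcript {t.name} is non-coding: no protein")
        return f">{record.lrg_id}{t.protein.name}\n{_wrap(t.protein.sequence)}\n"
    raise LrgError(f"unknown export {what!r} (genomic|cdna|protein)")


def export_bed(record: LrgRecord, mapping: AssemblyMapping) -> str:
    """BED12, one line per transcript, projected through ``mapping``.

    BED is 0-based half-open; the conversion from the internal 1-based
    inclusive coordinates happens here and only here.  Exons interrupted by
    a mapping diff are reported as errors per transcript line while other
    transcripts are still emitted.
    """
    lines = []
    for t in record.fixed.transcripts:
        try:
            lines.append(_bed_line(record, mapping, t))
        except UnmappablePositionError as exc:
            lines.append(f"# {record.lrg_id}{t.name}: unmappable exon: {exc}")
    return "\n".join(lines) + "\n"


def _project_interval(mapping: AssemblyMapping, start: int,
                      end: int) -> Tuple[int, int, int]:
    a = coord_map.map_lrg_to_other(mapping, start)
    b = coord_map.map_lrg_to_other(mapping, end)
    if a.strand != b.strand or abs(b.position - a.position) != end - start:
        raise UnmappablePositionError(
            f"interval {start}..{end} is interrupted by a mapping diff")
    lo, hi = sorted((a.position, b.position))
    return lo, hi, a.strand


def _bed_line(record: LrgRecord, mapping: AssemblyMapping,
              t: Transcript) -> str:
    projected = [_project_interval(mapping, e.lrg_start, e.lrg_end)
                 for e in t.exons]
    strand = projected[0][2]
    blocks = sorted((lo, hi) for lo, hi, _ in projected)
    chrom_start = blocks[0][0] - 1  # 1-based inclusive -> 0-based half-open
    chrom_end = blocks[-1][1]
    if t.coding_region:
        lo, hi, _ = _project_interval(mapping, t.coding_region.cds_start,
                                      t.coding_region.cds_end)
        thick_start, thick_end = lo - 1, hi
    else:
        thick_start = thick_end = chrom_start
    sizes = ",".join(str(hi - lo + 1) for lo, hi in blocks)
    starts = ",".join(str(lo - 1 - chrom_start) for lo, hi in blocks)
    return "\t".join(str(x) for x in (
        mapping.other_accession, chrom_start, chrom_end,
        f"{record.lrg_id}{t.name}", 0, "+" if strand == 1 else "-",
        thick_start, thick_end, "0,0,0", len(blocks), sizes, starts))


def export_gff3(record: LrgRecord) -> str:
    """GFF3 gene model on the record's own coordinates (1-based inclusive)."""
    lines = ["##gff-version 3",
             f"##sequence-region {record.lrg_id} 1 {len(record.fixed.sequence)}"]
    if record.fixed.transcripts:
        gene_start = min(t.span_start for t in record.fixed.transcripts)
        gene_end = max(t.span_end for t in record.fixed.transcripts)
        gid = f"{record.lrg_id}_gene"
        lines.append(_gff(record.lrg_id, "gene", gene_start, gene_end,
                          f"ID={gid}"))
        for t in record.fixed.transcripts:
            tid = f"{record.lrg_id}{t.name}"
            lines.append(_gff(record.lrg_id, "mRNA", t.span_start, t.span_end,
                              f"ID={tid};Parent={gid}"))
            for i, e in enumerate(t.exons, start=1):
                lines.append(_gff(record.lrg_id, "exon", e.lrg_start, e.lrg_end,
                                  f"ID={tid}.exon{i};Parent={tid}"))
            if t.coding_region:
                cr = t.coding_region
                for e in t.exons:
                    lo = max(e.lrg_start, cr.cds_start)
                    hi = min(e.lrg_end, cr.cds_end)
                    if lo <= hi:
                        lines.append(_gff(record.lrg_id, "CDS", lo, hi,
                                          f"ID={tid}.cds;Parent={tid}"))
    return "\n".join(lines) + "\n"


def _gff(seqid: str, ftype: str, start: int, end: int, attrs: str) -> str:
    return "\t".join((seqid, "lrgkit", ftype, str(start), str(end), ".",
                      "+", ".", attrs))
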