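"""Parse, format, and translate variant descriptions between reference frames.

Supported core: single-nucleotide substitutions in g./c. coordinates and
their p. consequences.  Deletions/duplications/insertions parse into a
lossless :class:`UnsupportedEdit` that formats back verbatim but cannot be
frame-translated.  Protein descriptions use 3-letter residue codes; the
synonymous consequence renders as ``p.(=)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Union

from . import coord_map, seq_ops
from .coord_map import CDS, UTR3, UTR5, CodingPosition
from .core_model import LrgRecord, Transcript
from .errors import (
    DeprecatedIvsError,
    HgvsParseError,
    LrgError,
    OutOfSpanError,
    RefMismatchError,
    UnknownFrameError,
)

# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Substitution:
    """g./c. single-base substitution ``ref>alt``."""

    ref: str
    alt: str

    def __str__(self) -> str:
        return f"{self.ref}>{self.alt}"


@dataclass(frozen=True)
class ProteinSubstitution:
    """p. substitution in 3-letter codes; alt ``Ter`` marks a stop gain."""

    ref: str
    alt: str


@dataclass(frozen=True)
class Synonymous:
    """No protein-level change; renders as ``p.(=)``."""


@dataclass(frozen=True)
class UnsupportedEdit:
    """Non-substitution edit kept verbatim (del/dup/ins/delins/...)."""

    text: str

    def __str__(self) -> str:
        return self.text


Edit = Union[Substitution, ProteinSubstitution, Synonymous, UnsupportedEdit]


@dataclass(frozen=True)
class VariantDescription:
    reference: Optional[str]  # "LRG_1", "LRG_1t1", "NM_000088.3", ... or None
    system: str  # "g" | "c" | "p"
    location: Union[int, CodingPosition, None]  # residue index for p.
    edit: Edit


# ---------------------------------------------------------------------------
# grammar
# ---------------------------------------------------------------------------

_LRG_REF_RE = re.compile(r"^LRG_[1-9][0-9]*(?:(?P<prod>[tp])(?P<num>[1-9][0-9]*))?$")
_ACCESSION_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*\.[0-9]+$")
_C_LOC_RE = re.compile(r"^(?P<star>\*)?(?P<anchor>-?[0-9]+)(?P<off>[+-][0-9]+)?")
_G_LOC_RE = re.compile(r"^[0-9]+")
_SUB_RE = re.compile(r"^(?P<ref>[ACGT])>(?P<alt>[ACGT])$")
_P_SUB_RE = re.compile(
    r"^(?P<ref>[A-Z][a-z]{2})(?P<pos>[1-9][0-9]*)(?P<alt>[A-Z][a-z]{2})$"
)
_IVS_RE = re.compile(
    r"^IVS(?P<intron>[0-9]+)(?P<sign>[+-])(?P<off>[0-9]+)"
    r"(?:(?P<ref>[ACGT])>(?P<alt>[ACGT]))?$"
)

_VALID_AA3 = frozenset(seq_ops.AA_1LETTER)


def _system_for_reference(reference: Optional[str], system: str, offset: int) -> None:
    if reference is None:
        return
    m = _LRG_REF_RE.match(reference)
    if m:
        prod = m.group("prod")
        expected = {"t": "c", "p": "p", None: "g"}[prod]
        if system != expected:
            raise HgvsParseError(
                f"reference {reference!r} implies system {expected!r}, "
                f"got {system!r}", offset)
        return
    if not _ACCESSION_RE.match(reference):
        raise HgvsParseError(f"unrecognized reference {reference!r}", 0)


def parse(text: str) -> VariantDescription:
    """Parse ``[reference:]system.location edit`` into a description.

    Raises :class:`HgvsParseError` with a character offset on malformed
    input, and :class:`DeprecatedIvsError` on IVS-style intron notation.
    """
    text = text.strip()
    reference: Optional[str] = None
    body = text
    body_off = 0
    if ":" in text:
        reference, body = text.split(":", 1)
        body_off = len(reference) + 1
        if not reference:
            raise HgvsParseError("empty reference before ':'", 0)

    if body.startswith("IVS"):
        raise DeprecatedIvsError(body)

    if len(body) < 2 or body[1] != "." or body[0] not in "gcp":
        raise HgvsParseError(
            f"expected 'g.', 'c.' or 'p.' prefix in {body!r}", body_off)
    system = body[0]
    rest = body[2:]
    rest_off = body_off + 2
    _system_for_reference(reference, system, 0)

    if system == "g":
        m = _G_LOC_RE.match(rest)
        if not m:
            raise HgvsParseError(f"expected genomic position in {rest!r}",
                                 rest_off)
        location: Union[int, CodingPosition] = int(m.group(0))
        edit = _parse_nt_edit(rest[m.end():], rest_off + m.end())
        return VariantDescription(reference, "g", location, edit)

    if system == "c":
        m = _C_LOC_RE.match(rest)
        if not m:
            raise HgvsParseError(f"expected coding position in {rest!r}",
                                 rest_off)
        anchor = int(m.group("anchor"))
        if anchor == 0:
            raise HgvsParseError("coding position 0 does not exist", rest_off)
        if m.group("star"):
            if anchor < 0:
                raise HgvsParseError("'*' positions are positive", rest_off)
            region = UTR3
        elif anchor < 0:
            region = UTR5
        else:
            region = CDS
        offset = int(m.group("off")) if m.group("off") else 0
        location = CodingPosition(region, anchor, offset)
        edit = _parse_nt_edit(rest[m.end():], rest_off + m.end())
        return VariantDescription(reference, "c", location, edit)

    # p.
    if rest == "(=)":
        return VariantDescription(reference, "p", None, Synonymous())
    m = _P_SUB_RE.match(rest)
    if not m:
        raise HgvsParseError(f"expected protein substitution in {rest!r}",
                             rest_off)
    ref3, alt3 = m.group("ref"), m.group("alt")
    for aa in (ref3, alt3):
        if aa not in _VALID_AA3:
            raise HgvsParseError(f"unknown residue code {aa!r}", rest_off)
    return VariantDescription(reference, "p", int(m.group("pos")),
                              ProteinSubstitution(ref3, alt3))


def _parse_nt_edit(text: str, offset: int) -> Edit:
    if not text:
        raise HgvsParseError("missing edit after position", offset)
    m = _SUB_RE.match(text)
    if m:
        return Substitution(m.group("ref"), m.group("alt"))
    if re.match(r"^(del|dup|ins|delins|inv)", text):
        return UnsupportedEdit(text)
    raise HgvsParseError(f"unparsable edit {text!r}", offset)


def format(v: VariantDescription) -> str:  # noqa: A001 - domain verb
    """Canonical text for a description; inverse of :func:`parse`."""
    prefix = f"{v.reference}:" if v.reference else ""
    if v.system == "p":
        if isinstance(v.edit, Synonymous):
            return f"{prefix}p.(=)"
        return f"{prefix}p.{v.edit.ref}{v.location}{v.edit.alt}"
    loc = str(v.location)
    return f"{prefix}{v.system}.{loc}{v.edit}"


# ---------------------------------------------------------------------------
# IVS conversion
# ---------------------------------------------------------------------------

def ivs_to_c(transcript: Transcript, ivs_text: str) -> VariantDescription:
    """Convert deprecated ``IVS<k>±<offset>`` notation to c. coordinates.

    ``IVS<k>+n`` anchors on the last base of exon *k*; ``IVS<k>-n`` on the
    first base of exon *k+1*.
    """
    m = _IVS_RE.match(ivs_text.strip())
    if not m:
        raise HgvsParseError(f"not an IVS description: {ivs_text!r}", 0)
    k = int(m.group("intron"))
    if not (1 <= k <= len(transcript.exons) - 1):
        raise OutOfSpanError(
            f"intron {k} does not exist: transcript {transcript.name} has "
            f"{len(transcript.exons)} exons"
        )
    offset = int(m.group("off"))
    if m.group("sign") == "+":
        boundary_g = transcript.exons[k - 1].lrg_end
        signed = offset
    else:
        boundary_g = transcript.exons[k].lrg_start
        signed = -offset
    base = coord_map.g_to_c(transcript, boundary_g)
    location = CodingPosition(base.region, base.anchor, signed)
    if m.group("ref"):
        edit: Edit = Substitution(m.group("ref"), m.group("alt"))
    else:
        raise HgvsParseError("IVS description lacks an edit", len(ivs_text))
    return VariantDescription(None, "c", location, edit)


# ---------------------------------------------------------------------------
# frame / system conversions
# ---------------------------------------------------------------------------

def _lrg_base(record: LrgRecord) -> str:
    return record.lrg_id


def g_variant_to_c(record: LrgRecord, transcript_name: str,
                   v: VariantDescription) -> VariantDescription:
    """Rewrite a genomic substitution in coding coordinates of one transcript.

    The stated reference base is checked against the record sequence; a
    disagreement raises :class:`RefMismatchError` rather than being
    silently corrected.
    """
    if v.system != "g":
        raise LrgError(f"expected a g. description, got {v.system!r}")
    if not isinstance(v.edit, Substitution):
        raise LrgError("only substitutions can be converted")
    transcript = record.transcript(transcript_name)
    g_pos = v.location
    actual = record.fixed.sequence[g_pos - 1]
    if actual != v.edit.ref:
        raise RefMismatchError(
            f"stated reference base {v.edit.ref} at g.{g_pos} differs from "
            f"record base {actual}"
        )
    c = coord_map.g_to_c(transcript, g_pos)
    reference = (f"{_lrg_base(record)}{transcript_name}"
                 if v.reference else None)
    return VariantDescription(reference, "c", c, v.edit)


def c_variant_to_g(record: LrgRecord, transcript_name: str,
                   v: VariantDescription) -> VariantDescription:
    """Inverse of :func:`g_variant_to_c`."""
    if v.system != "c":
        raise LrgError(f"expected a c. description, got {v.system!r}")
    if not isinstance(v.edit, Substitution):
        raise LrgError("only substitutions can be converted")
    transcript = record.transcript(transcript_name)
    g_pos = coord_map.c_to_g(transcript, v.location)
    actual = record.fixed.sequence[g_pos - 1]
    if actual != v.edit.ref:
        raise RefMismatchError(
            f"stated reference base {v.edit.ref} at {v.location} (g.{g_pos}) "
            f"differs from record base {actual}"
        )
    reference = _lrg_base(record) if v.reference else None
    return VariantDescription(reference, "g", g_pos, v.edit)


def c_variant_to_p(record: LrgRecord, transcript_name: str,
                   v: VariantDescription) -> VariantDescription:
    """Protein consequence of an exonic CDS substitution.

    Synonymous changes yield ``p.(=)``; a gained stop renders its alt
    residue as ``Ter``.  UTR and intronic inputs are refused.
    """
    if v.system != "c":
        raise LrgError(f"expected a c. description, got {v.system!r}")
    if not isinstance(v.edit, Substitution):
        raise LrgError("only substitutions can be converted")
    c = v.location
    if c.region != CDS or c.intron_offset != 0:
        raise OutOfSpanError(
            f"c.{c} is not an exonic CDS position; no protein consequence "
            "is computed"
        )
    transcript = record.transcript(transcript_name)

    # check stated ref base against the record
    g_pos = coord_map.c_to_g(transcript, c)
    actual = record.fixed.sequence[g_pos - 1]
    if actual != v.edit.ref:
        raise RefMismatchError(
            f"stated reference base {v.edit.ref} at c.{c} differs from "
            f"record base {actual}"
        )

    cr = transcript.coding_region
    cds = seq_ops.extract_cds(record.fixed.sequence, transcript.exons,
                              cr.cds_start, cr.cds_end)
    residue = coord_map.c_to_p(c)
    pos_in_codon = (c.anchor - 1) % 3
    codon = cds[3 * (residue - 1): 3 * residue]
    mutated = codon[:pos_in_codon] + v.edit.alt + codon[pos_in_codon + 1:]
    ref_aa = seq_ops.STANDARD_CODE[codon]
    alt_aa = seq_ops.STANDARD_CODE[mutated]

    pnum = transcript.name[1:]
    reference = f"{_lrg_base(record)}p{pnum}" if v.reference else None
    if ref_aa == alt_aa:
        return VariantDescription(reference, "p", residue, Synonymous())
    return VariantDescription(
        reference, "p", residue,
        ProteinSubstitution(seq_ops.AA_3LETTER[ref_aa],
                            seq_ops.AA_3LETTER[alt_aa]),
    )


def translate_reference_frame(record: LrgRecord, v: VariantDescription,
                              target_accession: str) -> VariantDescription:
    """Re-express a description against another declared reference frame.

    Frames flagged ``identical_to_lrg`` carry coordinates over unchanged;
    assembly-mapping frames project g. positions through the mapping,
    complementing the edit bases on the minus strand.
    """
    available = []
    for aset in record.updatable.annotation_sets:
        for xref in aset.xrefs:
            available.append(xref.versioned_accession)
            if xref.versioned_accession == target_accession and xref.identical_to_lrg:
                return VariantDescription(target_accession, v.system,
                                          v.location, v.edit)
        for mapping in aset.mappings:
            available.append(mapping.other_accession)
            if mapping.other_accession == target_accession:
                if v.system != "g":
                    raise LrgError(
                        "assembly-frame translation is defined for g. "
                        f"descriptions only, got {v.system!r}"
                    )
                if not isinstance(v.edit, Substitution):
                    raise LrgError("only substitutions can be frame-translated")
                mapped = coord_map.map_lrg_to_other(mapping, v.location)
                edit = v.edit
                if mapped.strand == -1:
                    edit = Substitution(seq_ops.complement_base(edit.ref),
                                        seq_ops.complement_base(edit.alt))
                return VariantDescription(target_accession, "g",
                                          mapped.position, edit)
    raise UnknownFrameError(
        f"{target_accession!r} is not a declared frame of {record.lrg_id}; "
        f"available: {', '.join(sorted(set(available))) or 'none'}"
    )
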