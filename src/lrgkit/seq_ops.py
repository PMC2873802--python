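"""Elementary sequence computations: reverse complement, splicing, translation.

All coordinates handled here are 1-based and fully inclusive.  Only the
alphabet ``{A, C, G, T, N}`` is accepted; degenerate IUPAC codes are
rejected so that every downstream computation is deterministic.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence, Tuple

from .errors import LrgError

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Standard genetic code, DNA triplets -> one-letter amino acid, "*" = stop.
STANDARD_CODE: Mapping[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in STANDARD_CODE.items() if aa == "*")

#: One-letter -> three-letter residue codes (plus the stop marker "Ter").
AA_3LETTER: Mapping[str, str] = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter",
}

AA_1LETTER: Mapping[str, str] = {v: k for k, v in AA_3LETTER.items()}


def check_alphabet(seq: str, *, allow_n: bool = True) -> None:
    """Raise :class:`LrgError` naming the first foreign character."""
    allowed = DNA_ALPHABET if allow_n else DNA_ALPHABET - {"N"}
    for i, base in enumerate(seq, start=1):
        if base not in allowed:
            raise LrgError(f"invalid base {base!r} at position {i}")


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution."""
    check_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    if base not in DNA_ALPHABET:
        raise LrgError(f"invalid base {base!r}")
    return base.translate(_COMPLEMENT)


def _interval(exon) -> Tuple[int, int]:
    if hasattr(exon, "lrg_start"):
        return exon.lrg_start, exon.lrg_end
    start, end = exon
    return start, end


def splice(genomic: str, exons: Iterable) -> str:
    """Concatenate the genomic slices covered by ``exons`` in order.

    ``exons`` may be ``Exon`` objects or ``(start, end)`` pairs, 1-based
    inclusive.
    """
    parts = []
    for exon in exons:
        start, end = _interval(exon)
        if start < 1 or end > len(genomic):
            raise LrgError(
                f"exon {start}..{end} outside sequence of length {len(genomic)}"
            )
        if end < start:
            raise LrgError(f"exon end {end} < start {start}")
        parts.append(genomic[start - 1 : end])
    return "".join(parts)


def translate(cds: str, table: Mapping[str, str] = STANDARD_CODE) -> str:
    """Translate a CDS (start through stop codon) to a protein string.

    The terminal stop codon is required and dropped from the result.  A CDS
    must be at least two codons, a multiple of three, free of N, and contain
    no internal stop.
    """
    if len(cds) % 3 != 0:
        raise LrgError(f"CDS length {len(cds)} is not a multiple of 3")
    if len(cds) < 6:
        raise LrgError(f"CDS length {len(cds)} shorter than two codons")
    if "N" in cds:
        raise LrgError(f"CDS contains N at position {cds.index('N') + 1}")
    check_alphabet(cds, allow_n=False)
    residues = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        aa = table[codon]
        if aa == "*":
            if i != n_codons - 1:
                raise LrgError(
                    f"internal stop codon {codon} at CDS position {3 * i + 1}"
                )
            return "".join(residues)
        residues.append(aa)
    raise LrgError("CDS does not end with a stop codon")


def codon_span(residue_index: int) -> Tuple[int, int, int]:
    """The three CDS-anchored coordinates of codon ``residue_index``."""
    if residue_index < 1:
        raise LrgError(f"residue index must be positive, got {residue_index}")
    return (3 * residue_index - 2, 3 * residue_index - 1, 3 * residue_index)


def extract_cds(genomic: str, exons: Sequence, cds_start: int, cds_end: int) -> str:
    """Exonic sequence between the CDS bounds (both inclusive, genomic)."""
    parts = []
    for exon in exons:
        start, end = _interval(exon)
        lo, hi = max(start, cds_start), min(end, cds_end)
        if lo <= hi:
            parts.append(genomic[lo - 1 : hi])
    return "".join(parts)
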