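# lrgkit

A library and CLI for two-layer locus reference gene records: a gene-record
data model with an immutable **fixed-annotation layer** (genomic sequence,
transcripts, exon markup, CDS bounds, cDNA and protein sequences) and a
date-stamped **updatable-annotation layer** (assembly mappings,
cross-references, legacy numbering maps, overlap reports), together with the
full coordinate algebra for describing sequence variants in genomic (g.),
coding-DNA (c.) and protein (p.) coordinates.

Features:

* **Record model & validation** (`lrgkit.core_model`) — typed record
  structure, ~25 machine-coded consistency checks (findings, never
  exceptions), a SHA-256 fixed-layer digest over a canonical serialization,
  and a new-ID policy check (any fixed-layer change requires a new record
  id; updatable edits never do).
* **Sequence primitives** (`lrgkit.seq_ops`) — reverse complement, exon
  splicing, CDS translation with the standard genetic code, codon-span
  arithmetic.
* **Coordinate algebra** (`lrgkit.coord_map`) — g.↔c. conversion with
  intron offsets (`c.2451+77`) and UTR numbering (`c.-14`, `c.*46`), c.→p.
  codon arithmetic, strand-aware record↔assembly mapping with sequence
  diffs, legacy exon-label and residue renumbering.
* **Variant descriptions** (`lrgkit.hgvs_names`) — parse/format of
  substitution descriptions (`LRG_1t1:c.572G>C`), conversion between g., c.
  and p. systems with reference-base checking, deprecated-IVS conversion,
  and translation between declared reference frames (identity
  cross-references and assembly mappings, with base complementation on the
  minus strand).
* **I/O** (`lrgkit.lrg_xml_io`) — a documented, versioned XML dialect with
  separate fixed/updatable sections, structural schema validation, plain
  text rendering, and FASTA / BED12 / GFF3 export.
* **Synthetic records** (`lrgkit.fixtures`) — deterministic record
  construction from parts, seeded random genes with exhaustive per-base
  oracle tables, a multi-transcript fixture, and an engineered
  worked-example record.

All coordinates are **1-based, fully inclusive** everywhere; the only
0-based half-open coordinates appear in BED export, converted at that
boundary only.

## CLI

The `lrg` entry point bundles everything:

```sh
lrg fixture --name col1a1-like --out record.xml   # engineered example record
lrg validate --record record.xml                  # findings as TSV; --strict
lrg digest --record record.xml                    # sha256 <hex>
lrg map --record record.xml --from lrg --to assembly --pos 1
lrg map --record record.xml --from c --to p --pos 572
lrg hgvs parse "LRG_13:g.8290C>A"
lrg hgvs convert "LRG_1t1:c.572G>C" --record record.xml --to p
lrg hgvs convert "LRG_1:g.8463G>C" --record record.xml --to NG_007400.1
lrg convert --record record.xml --to {fasta|bed|gff3|text|xml}
lrg check-id-policy --existing old.xml --proposed new.xml
```

Machine output goes to stdout (or `--out`); diagnostics to stderr.
Exit codes: 0 success, 1 domain/validation failure, 2 usage error.

## Scope notes

Substitutions are the supported edit core; del/dup/ins parse losslessly but
cannot be frame-translated. Non-coding (n.) coordinates, variant
normalization (3′-shifting), multi-record projection chains and variant
aggregation are out of scope.
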