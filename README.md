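# lrgkit

Build, validate and query **locus reference genomic (LRG-style) records** —
stable, versionless reference sequences for reporting clinically relevant
variants.

Diagnostic laboratories report variants in HGVS notation against a reference
sequence. When that reference is a versioned transcript or a moving genome
assembly, reports drift and become ambiguous over time. An LRG-style record
fixes this: one accession of the form `LRG_<number>` bundles, for one locus,

* an immutable **fixed section**: the genomic sequence (by default extending
  5 kb upstream of the first exon and 2 kb downstream of the last), the
  reporting transcripts `t1, t2, …` with their cDNAs, coding regions and
  proteins `p1, p2, …`, and a stable exon numbering shared across
  transcripts (distinct exons numbered consecutively 5'→3'); and
* a replaceable **updatable section**: alignments to genome assemblies
  (contiguous spans plus enumerated sequence differences), third-party gene
  annotation, legacy numbering schemes and notes.

The fixed section never changes — its SHA-256 content digest makes that
checkable — so `LRG_1t1:c.572G>C` means the same thing forever. `lrgkit`
implements the record model, its XML persistence, record construction from a
genome + gene model, the exon numbering scheme, coordinate conversion among
the record's systems

```
g.   genomic position on the record          LRG_1:g.8463G>C
c.   coding transcript (−N UTR5, *N UTR3,    LRG_1t1:c.572G>C
     N±k intronic)
n.   non-coding transcript                   LRG_163t1:n.5C>T
p.   protein, 3-letter codes                 LRG_1p1:p.Gly191Ala
```

and assembly remapping, with `codon_of(c) = ⌈c/3⌉` tying the c. and p.
systems together (`c.572` → codon 191 — which is why `c.572G>C` in a glycine
codon reports as `p.Gly191Ala`).

## Worked example

Everything runs on synthetic data; no external files are needed. From
`examples/build_a_record.py`:

```python
from lrgkit import FixtureSpec, build_record, make_fixture, validate_record

genome, model = make_fixture(FixtureSpec(seed=7))   # ~20 kb contig, 4-exon gene
record = build_record(genome, model, lrg_number=9001)
```

prints

```
record        : LRG_9001 (pending)
gene          : SYN7, strand -1
genomic length: 8298 bp
first exon at : 5001 (=> 5000 bp upstream flank)
downstream    : 2000 bp after last exon
transcripts   : ['t1', 't2']
t1 exon labels: (1, 2, 3, 4)
t1 CDS        : c.1..57 -> protein of 18 aa
validation    : clean
fixed digest  : 53311baa8cfc4486... (stable for this content)
```

The gene is on the minus strand, yet the first exon starts at position 5001:
the record stores the transcription strand 5'→3', so "5 kb upstream" is
literally 5000 bases before the first exon, and the strand is carried by the
assembly mapping instead. Converting a variant between systems
(`examples/hgvs_parse_and_convert.py`):

```
genomic    : LRG_1:g.5106T>C
coding     : LRG_1t1:c.11T>C   (same base, transcript coordinates)
protein    : LRG_1p1:p.Leu4Pro   (codon 4, middle position)
```

The other examples show stable exon numbering under transcript addition
(existing labels never change; a novel exon between labels 1 and 2 gets
label 4) and diff-aware remapping to an assembly, including positions inside
an insertion that have no counterpart on the other side.

A CLI wraps the same operations for shell use:

```sh
lrgkit build genome.fasta gene.gff3 --lrg-number 1 --out LRG_1.xml
lrgkit convert LRG_1.xml 'LRG_1t1:c.572G>C' --to p
lrgkit remap LRG_1.xml --assembly GRCh38 8463
lrgkit exon-table LRG_1.xml
lrgkit fasta LRG_1.xml --selector t1
lrgkit parse 'LRG_1:g.8463G>C'
lrgkit validate LRG_1.xml
```

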