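# Methods

## The record model

Clinical variant reporting needs a reference sequence that never changes.
Genome assemblies are versioned and patched; transcript records are
re-versioned as annotation improves; and a variant report like `c.572G>C` is
only meaningful relative to one exact sequence. The locus reference genomic
(LRG-style) record model solves this by issuing, per clinically relevant
locus, a versionless accession (`LRG_<number>`) over a record with two parts:

* a **fixed section** — the genomic sequence for the locus, the transcripts
  and proteins the community reports against, and a locus-specific exon
  numbering. Nothing here may ever change after release; even a discovered
  sequence error is handled by issuing a *successor* record with a new
  accession and annotating the old one, never by editing it.
* an **updatable section** — everything that legitimately changes over time:
  alignments of the record to genome assemblies, third-party gene
  annotation, legacy exon/amino-acid numbering schemes, free-text notes.

`lrgkit` implements this model: construction of records from a genome +
gene model, XML persistence, validation, the exon numbering scheme,
coordinate conversion among the record's systems (g./c./n./p.) and to and
from assembly coordinates, and an HGVS grammar restricted to LRG-anchored
substitutions.

Immutability is made checkable rather than merely promised: `fixed_digest`
is a SHA-256 over a canonical serialisation of the fixed section (fields in
a documented order, sequences uppercased), so "the fixed section did not
change" is a string comparison. The digest ignores the updatable section by
construction, and any single-character change to any fixed sequence changes
it.

## Record construction

`build_record` takes a source genome and a gene model (exons, optional CDS,
requested transcripts as exon subsets) and cuts the record's genomic
sequence from `first exon − flank_up` to `last exon + flank_down`, measured
on the transcription strand over the union of all requested transcripts'
exons. Defaults are `flank_up=5000`, `flank_down=2000` bp — the standard
extent for such records; loci needing more context (promoters, regulatory
elements) simply widen the flanks, there is no promoter detection. Flanks
are clipped at contig edges with a logged warning rather than an error,
since real contigs are finite.

Minus-strand genes are stored 5'→3' on the record's sequence (i.e. the slice
is reverse-complemented) with strand −1 recorded in the assembly mapping.
This makes every transcript-level computation strand-free inside the record;
strand only re-enters when mapping back to the assembly.

Per transcript, the cDNA is the exon concatenation (poly-A tails, being
post-transcriptional, never appear), and a coding region is attached iff the
transcript contains *every* model exon overlapping the CDS span — a
transcript missing a coding exon is emitted non-coding rather than given a
frameshifted CDS. The CDS must be a multiple of 3, start-to-stop, with no
internal stop; the protein is its standard-code translation minus the
terminal stop. Only the standard nuclear genetic code is supported.

## Exon numbering

The union of all fixed transcripts' distinct exons is numbered consecutively
5'→3'; each transcript then carries the projection of those labels. "Distinct
exon" means exact `(start, end)` identity — overlapping-but-unequal exons get
distinct labels, the only rule that never merges biologically different
boundaries. Ties on start are broken by end (shorter exon first).

`extend_numbering` models post-release additions: existing labels are
immutable; novel spans get the next unused integers in 5'→3' order, with an
override map for community-decreed labels (an override may not collide with
an assigned label). Note that an override introducing a gap in the label
sequence will be flagged by `validate_record`, which expects labels 1..K;
records produced by this package's own operations always satisfy that.

## Coordinate systems

All coordinates are 1-based fully closed, matching HGVS usage.

* **g.** — position on the record's genomic sequence.
* **c.** — HGVS coding coordinates: CDS base `N`, 5'UTR `-N`, 3'UTR `*N`,
  intronic `anchor±k`. Intronic positions anchor on the nearest exon
  boundary; offset `k` from the upstream boundary goes to the `+` side iff
  `k ≤ (I+1)//2` for intron length `I`, so the exact-tie middle base of an
  odd-length intron goes upstream. Positions beyond the transcript ends
  continue the UTR counts (`-N` / `*N`) without intron offsets, which keeps
  `g_to_c`/`c_to_g` mutually inverse over the whole record sequence.
* **n.** — non-coding transcripts: the 1-based index into the exon
  concatenation. Intronic n. positions are not supported in v1.
* **p.** — `codon_of(c) = (⌈c/3⌉, ((c−1) mod 3)+1)`; `predict_protein_change`
  mutates the affected codon only and translates old/new codons, rendering
  3-letter codes, stop as `Ter`, synonymous as `=`. Substitutions in the stop
  codon are allowed (residue L+1, reference `Ter`).

## Assembly remapping

An assembly mapping is an ordered set of contiguous alignment spans (all on
one strand) plus enumerated differences: `mismatch` (equal-length, shifts
nothing, but surfaced so allele checking can use it), `lrg_insertion`
(bases only on the record) and `assembly_insertion` (bases only on the
assembly). Validation enforces per-span length conservation:
`assembly length = LRG length − Σ lrg_insertions + Σ assembly_insertions`.

Position mapping applies cumulative indel shifts within the span, then
projects by strand (`other_start + off` or `other_end − off`). Three failure
modes are distinguished deliberately: outside the mapped range
(`OutOfRangeError`), between spans (`UnmappedGapError`), and inside an
insertion with no counterpart (`UnmappableDiffError`). Alleles are not
reverse-complemented by the remapper; the strand is returned so callers can
transform alleles themselves. Multiple assemblies are held as independent
mappings (at most one per assembly name); no shared span boundaries are
assumed.

## HGVS grammar

v1 parses exactly the LRG-anchored substitution grammar:
`LRG_<n>[t<k>|p<k>]:<g|c|n|p>.<position><ref>><alt>` for nucleotides and
3-letter protein missense (`p.Gly191Ala`, synonymous `p.Gly191=`). One-letter
protein codes are rejected with a hint rather than silently converted, and
versioned accessions (`LRG_1.2`) are rejected outright — accessions are never
versioned in this scheme. Deletions, duplications, insertions and other
classes parse to a structured "unsupported" value that re-renders verbatim,
so pipelines that merely carry such expressions do not lose them.
`convert_variant` supports g↔c, g↔n and c→p (also g→p through the coding
transcript), always verifying the stated reference allele against the
record; p.→nucleotide is rejected as ambiguous.

## Synthetic data

`make_fixture` generates the seeded genomes and gene models the test suite
and examples run on. Defaults describe a small but structurally complete
locus: a 20 kb contig (room for the 5 kb/2 kb flanks without clipping), 4
exons of 90–240 bp separated by 80–600 bp introns, random strand, balanced
GC, one coding transcript over all exons plus one random exon-subset
transcript. The CDS is carved directly into the exonic sequence in
transcription order — `ATG`, random sense codons, a stop — so every fixture
translates cleanly by construction. Exon sizes are realistic for human genes;
the short introns and the single-gene, single-contig world are not: fixtures
contain no repeats, no alternative CDSs, no overlapping genes, no assembly
patches. Passing tests therefore demonstrate the coordinate arithmetic,
numbering and persistence logic, not robustness to the annotation ambiguity
of real loci, and the generator cannot produce the curated content of any
real record.

For exhaustive per-base checks the suite uses smaller fixtures (≈6 kb
genomes, 3 exons, flanks 300/150) so full scans stay fast; the XML round-trip
suite uses 200 seeds at ≈9 kb. These sizes are chosen so the whole default
suite completes in a few seconds while still covering every code path.

## Numerical / degenerate-input choices

* Validation returns violations as data (type, field, rule, severity), never
  exceptions; a fixed section with zero transcripts is a warning, not an
  error, since records may exist for non-genic loci.
* `write_lrg` refuses error-severity violations unless forced; forced writes
  log a warning.
* Sequences are stored uppercase and case-folded on read; `N` is accepted in
  genomic sequence, and codons containing `N` translate to `X`.
* Empty requester lists, diff-free mappings and single-exon genes are all
  legal and covered by tests.

## Known limitations

* No support for the official LRG XML schema v1.8 (the dialect here is
  self-describing but minimal), and no XSD validation.
* Substitutions only in the HGVS layer; no normalisation/left-alignment, no
  intronic n., no mitochondrial code, no NC_/NM_/ENST references.
* Transcript *selection* — deciding which transcripts belong in a fixed
  section — is human judgement and out of scope; the builder takes requested
  transcripts as given.
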