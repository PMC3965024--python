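"""Domain model for locus reference genomic (LRG-style) records.

An LRG-style record bundles everything needed to report variants at one
clinically relevant locus: a genomic reference sequence, the transcripts and
proteins the community reports against, and a locus-specific exon numbering
scheme. The record is split into two sections:

* the **fixed section** — sequences, identifiers and exon numbering that are
  guaranteed never to change once the record is public; and
* the **updatable section** — assembly mappings, third-party gene annotation,
  legacy numbering schemes and free-text notes, replaced wholesale on refresh.

Records carry versionless accessions of the form ``LRG_<number>``. If a locus
ever needs a corrected record, a *new* accession is issued and the old record
is annotated as superseded — the fixed content itself is immutable, which is
what makes variant reports against it stable over time.

All coordinates in this package are 1-based and fully closed, matching HGVS
usage.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "ExonSpan",
    "FixedProtein",
    "FixedTranscript",
    "ExonNumbering",
    "FixedSection",
    "MappingSpan",
    "SequenceDiff",
    "AssemblyMapping",
    "AnnotatedTranscript",
    "GeneAnnotation",
    "AnnotationSet",
    "LegacyNumbering",
    "UpdatableSection",
    "LrgRecord",
    "Violation",
    "validate_record",
    "fixed_digest",
    "replace_updatable",
    "mark_superseded",
    "LRG_ID_RE",
]

LRG_ID_RE = re.compile(r"^LRG_[1-9]\d*$")
_DNA_RE = re.compile(r"^[ACGTN]+$")
_STOPS = {"TAA", "TAG", "TGA"}

_CODON_TABLE = {}


def _codon_table() -> dict:
    # built lazily from Biopython's standard table
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


def translate_cds(cds: str) -> str:
    """Translate a DNA coding sequence with the standard genetic code.

    Stop codons become ``*``. Codons containing ``N`` become ``X``.
    """
    table = _codon_table()
    return "".join(
        table.get(cds[i : i + 3], "X") for i in range(0, len(cds) - 2, 3)
    )


@dataclass(frozen=True)
class ExonSpan:
    """A 1-based, fully closed interval on the LRG genomic sequence."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class FixedProtein:
    """A protein product in the fixed section, named ``p<k>`` after its transcript."""

    name: str
    sequence: str  # 1-letter amino acids, no stop character


@dataclass(frozen=True)
class FixedTranscript:
    """A reporting transcript in the fixed section.

    ``exons`` are spans on the LRG genomic sequence, ascending and
    non-overlapping; ``cdna_sequence`` is their concatenation (the poly-A
    tail, being post-transcriptional, is never part of it). ``coding_region``
    gives the CDS as 1-based inclusive cDNA positions spanning the start
    codon through the stop codon; it is present exactly when ``protein`` is.
    """

    name: str
    exons: tuple[ExonSpan, ...]
    cdna_sequence: str
    coding_region: Optional[tuple[int, int]] = None
    protein: Optional[FixedProtein] = None

    @property
    def cdna_length(self) -> int:
        return len(self.cdna_sequence)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic extent (first exon start, last exon end)."""
        return self.exons[0].start, self.exons[-1].end


@dataclass(frozen=True, eq=False)
class ExonNumbering:
    """The locus-specific stable exon labels shared across transcripts.

    Every distinct exon — identified by its exact (start, end) span — carries
    one positive-integer label. The initial assignment numbers the union of
    all fixed transcripts' exons consecutively 5'-3'; labels added later for
    new transcripts never disturb existing ones.
    """

    labels: dict  # {(start, end): int}
    per_transcript: dict  # {transcript name: (label, ...)}

    def __eq__(self, other):
        if not isinstance(other, ExonNumbering):
            return NotImplemented
        return (
            self.labels == other.labels
            and self.per_transcript == other.per_transcript
        )

    def label_of(self, span: ExonSpan) -> int:
        return self.labels[(span.start, span.end)]


@dataclass(frozen=True)
class FixedSection:
    """The immutable core of a record; see :func:`fixed_digest`."""

    hgnc_symbol: str
    requesters: tuple[str, ...]
    genomic_sequence: str
    transcripts: tuple[FixedTranscript, ...]
    numbering: ExonNumbering

    def transcript(self, name: str) -> FixedTranscript:
        for t in self.transcripts:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def digest(self) -> str:
        return fixed_digest(self)


@dataclass(frozen=True)
class MappingSpan:
    """One contiguous alignment block between LRG and assembly coordinates."""

    lrg_start: int
    lrg_end: int
    other_start: int
    other_end: int
    strand: int  # +1 or -1


@dataclass(frozen=True)
class SequenceDiff:
    """A point difference between the LRG sequence and the assembly.

    kind is one of:

    * ``mismatch`` — equal-length substitution, both alleles non-empty;
    * ``lrg_insertion`` — bases present on the LRG but absent from the
      assembly (``other_allele`` empty; ``other_start == other_end`` anchor
      the flanking assembly base);
    * ``assembly_insertion`` — bases present on the assembly but absent from
      the LRG (``lrg_allele`` empty; ``lrg_start == lrg_end`` anchor the LRG
      base after which the insertion sits).
    """

    kind: str
    lrg_start: int
    lrg_end: int
    other_start: int
    other_end: int
    lrg_allele: str = ""
    other_allele: str = ""


@dataclass(frozen=True)
class AssemblyMapping:
    """Alignment of the LRG genomic sequence to one genome assembly.

    Ordered contiguous spans plus the enumerated sequence differences inside
    them. All spans share one strand.
    """

    assembly: str
    other_name: str
    spans: tuple[MappingSpan, ...]
    diffs: tuple[SequenceDiff, ...] = ()

    @property
    def strand(self) -> int:
        return self.spans[0].strand if self.spans else 1


@dataclass(frozen=True)
class AnnotatedTranscript:
    name: str
    exons: tuple[ExonSpan, ...]


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene reported by an annotation source, in LRG coordinates."""

    symbol: str
    start: int
    end: int
    partial: bool = False
    synonyms: tuple[str, ...] = ()
    xrefs: tuple[tuple[str, str], ...] = ()  # (database, identifier)
    transcripts: tuple[AnnotatedTranscript, ...] = ()


ANNOTATION_SOURCES = ("NCBI", "Ensembl", "LSDB", "community")


@dataclass(frozen=True)
class AnnotationSet:
    """Third-party annotation of the LRG region from one source.

    Fixed-section transcripts echoed here are listed in
    ``fixed_transcript_marks`` so displays can distinguish them from other
    transcripts the source annotates.
    """

    source: str
    genes: tuple[GeneAnnotation, ...] = ()
    fixed_transcript_marks: tuple[str, ...] = ()


@dataclass(frozen=True, eq=False)
class LegacyNumbering:
    """A community exon/amino-acid numbering scheme predating the record."""

    name: str
    exon_map: dict  # {LRG exon label (int): legacy label (str)}
    aa_offset: Optional[int] = None

    def __eq__(self, other):
        if not isinstance(other, LegacyNumbering):
            return NotImplemented
        return (
            self.name == other.name
            and self.exon_map == other.exon_map
            and self.aa_offset == other.aa_offset
        )


@dataclass(frozen=True)
class UpdatableSection:
    """The replaceable half of a record.

    ``extras`` holds serialized XML for elements the reader did not
    recognize, so files written by richer dialects survive a read/write
    round trip byte-for-content.
    """

    mappings: tuple[AssemblyMapping, ...] = ()
    annotation_sets: tuple[AnnotationSet, ...] = ()
    legacy_numberings: tuple[LegacyNumbering, ...] = ()
    notes: tuple[str, ...] = ()
    extras: tuple[str, ...] = ()

    def mapping_for(self, assembly: str) -> AssemblyMapping:
        for m in self.mappings:
            if m.assembly == assembly:
                return m
        raise KeyError(assembly)


@dataclass(frozen=True)
class LrgRecord:
    """One locus record: versionless accession, fixed + updatable sections."""

    lrg_id: str
    status: str  # "pending" or "public"
    fixed: FixedSection
    updatable: UpdatableSection

    @property
    def fixed_digest(self) -> str:
        return fixed_digest(self.fixed)


# ---------------------------------------------------------------------------
# digest


def fixed_digest(fixed: FixedSection) -> str:
    """SHA-256 digest of a canonical serialization of the fixed section.

    The canonical form lists fields in a documented order with uppercase
    sequences, so the digest is stable across XML round trips, independent of
    the updatable section, and changes for any single-character change in any
    fixed-section sequence.
    """
    parts = [f"hgnc={fixed.hgnc_symbol}"]
    parts.extend(f"requester={r}" for r in fixed.requesters)
    parts.append(f"sequence={fixed.genomic_sequence.upper()}")
    for t in fixed.transcripts:
        ex = ",".join(f"{e.start}-{e.end}" for e in t.exons)
        cds = (
            f"{t.coding_region[0]}..{t.coding_region[1]}"
            if t.coding_region
            else "-"
        )
        prot = f"{t.protein.name}:{t.protein.sequence.upper()}" if t.protein else "-"
        parts.append(
            f"transcript={t.name};exons={ex};"
            f"cdna={t.cdna_sequence.upper()};cds={cds};protein={prot}"
        )
    for (s, e), lab in sorted(fixed.numbering.labels.items()):
        parts.append(f"exonlabel={s}-{e}:{lab}")
    for name in sorted(fixed.numbering.per_transcript):
        labs = ",".join(str(x) for x in fixed.numbering.per_transcript[name])
        parts.append(f"labels={name}:{labs}")
    return hashlib.sha256("\n".join(parts).encode("utf-8")).hexdigest()


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Violation:
    """One broken invariant: the type, field and rule it names are data, not
    an exception — callers decide what to do with them."""

    type_name: str
    field: str
    rule: str
    severity: str = "error"  # "error" or "warning"

    def __str__(self) -> str:
        return f"[{self.severity}] {self.type_name}.{self.field}: {self.rule}"


def _check_transcript(
    t: FixedTranscript, index: int, genome: str, out: list[Violation]
) -> None:
    bad = lambda fld, rule: out.append(Violation("FixedTranscript", fld, rule))

    expected = f"t{index}"
    if t.name != expected:
        bad("name", f"expected consecutive name {expected!r}, found {t.name!r}")

    prev_end = 0
    for ex in t.exons:
        if ex.start > ex.end:
            bad("exons", f"exon {ex.start}-{ex.end} has non-positive length")
        if ex.start < 1 or ex.end > len(genome):
            bad(
                "exons",
                f"exon {ex.start}-{ex.end} outside genomic sequence "
                f"[1, {len(genome)}]",
            )
        if ex.start <= prev_end:
            bad("exons", f"exon {ex.start}-{ex.end} overlaps or disorders previous")
        prev_end = ex.end
    if not t.exons:
        bad("exons", "transcript has no exons")
        return

    concat = "".join(genome[e.start - 1 : e.end] for e in t.exons)
    if t.cdna_sequence != concat:
        if t.cdna_sequence.startswith(concat) and set(
            t.cdna_sequence[len(concat) :]
        ) == {"A"}:
            bad(
                "cdna_sequence",
                "trailing poly-A run not present in the exon concatenation; "
                "poly-A tails are removed from all transcripts",
            )
        else:
            bad(
                "cdna_sequence",
                "cDNA does not equal the concatenation of genomic exon slices",
            )

    if (t.coding_region is None) != (t.protein is None):
        bad(
            "coding_region",
            "coding_region and protein must be present or absent together",
        )
    if t.coding_region is not None:
        cs, ce = t.coding_region
        if not (1 <= cs <= ce <= len(t.cdna_sequence)):
            bad("coding_region", f"CDS {cs}..{ce} outside cDNA [1, {len(t.cdna_sequence)}]")
            return
        if (ce - cs + 1) % 3 != 0:
            bad("coding_region", f"CDS length {ce - cs + 1} not divisible by 3")
            return
        cds = t.cdna_sequence[cs - 1 : ce]
        aa = translate_cds(cds)
        if "*" in aa[:-1]:
            bad("coding_region", "internal stop codon in CDS")
        if not aa.endswith("*"):
            bad("coding_region", "CDS does not end with a stop codon")
        if t.protein is not None:
            if not t.protein.sequence:
                out.append(Violation("FixedProtein", "sequence", "empty protein"))
            if "*" in t.protein.sequence:
                out.append(
                    Violation("FixedProtein", "sequence", "stop character in protein")
                )
            expected_p = f"p{index}"
            if t.protein.name != expected_p:
                out.append(
                    Violation(
                        "FixedProtein",
                        "name",
                        f"expected {expected_p!r} to match transcript index, "
                        f"found {t.protein.name!r}",
                    )
                )
            if aa.endswith("*") and t.protein.sequence != aa[:-1]:
                out.append(
                    Violation(
                        "FixedProtein",
                        "sequence",
                        "protein is not the translation of the coding region "
                        "(standard code, terminal stop excluded)",
                    )
                )


def _check_numbering(fixed: FixedSection, out: list[Violation]) -> None:
    num = fixed.numbering
    labels = list(num.labels.values())
    if len(set(labels)) != len(labels):
        out.append(
            Violation("ExonNumbering", "labels", "two distinct spans share a label")
        )
    if labels and sorted(labels) != list(range(1, len(labels) + 1)):
        out.append(
            Violation(
                "ExonNumbering",
                "labels",
                f"labels are not 1..{len(labels)} consecutive",
            )
        )
    names = {t.name for t in fixed.transcripts}
    if set(num.per_transcript) != names:
        out.append(
            Violation(
                "ExonNumbering",
                "per_transcript",
                "per-transcript label rows do not match the transcript list",
            )
        )
        return
    for t in fixed.transcripts:
        want = []
        for ex in t.exons:
            key = (ex.start, ex.end)
            if key not in num.labels:
                out.append(
                    Violation(
                        "ExonNumbering",
                        "labels",
                        f"exon {key} of {t.name} has no label",
                    )
                )
                break
            want.append(num.labels[key])
        else:
            if tuple(num.per_transcript[t.name]) != tuple(want):
                out.append(
                    Violation(
                        "ExonNumbering",
                        "per_transcript",
                        f"row for {t.name} disagrees with its exon labels",
                    )
                )


def _span_length_ok(span: MappingSpan, diffs: tuple[SequenceDiff, ...]) -> bool:
    lrg_len = span.lrg_end - span.lrg_start + 1
    other_len = span.other_end - span.other_start + 1
    ins_lrg = sum(
        len(d.lrg_allele)
        for d in diffs
        if d.kind == "lrg_insertion" and span.lrg_start <= d.lrg_start <= span.lrg_end
    )
    ins_other = sum(
        len(d.other_allele)
        for d in diffs
        if d.kind == "assembly_insertion"
        and span.lrg_start <= d.lrg_start <= span.lrg_end
    )
    return other_len == lrg_len - ins_lrg + ins_other


def _check_mapping(
    m: AssemblyMapping, genome: str, out: list[Violation]
) -> None:
    bad = lambda fld, rule: out.append(Violation("AssemblyMapping", fld, rule))
    if not m.spans:
        bad("spans", "mapping has no spans")
        return
    strands = {s.strand for s in m.spans}
    if len(strands) > 1:
        bad("spans", "spans do not share one strand value")
    prev = 0
    for s in m.spans:
        if s.lrg_end < s.lrg_start or s.other_end < s.other_start:
            bad("spans", f"span {s} has negative length")
        if s.lrg_start <= prev:
            bad("spans", "spans overlap or are not ascending in LRG coordinates")
        if s.lrg_end > len(genome):
            bad("spans", f"span end {s.lrg_end} beyond genomic sequence")
        prev = s.lrg_end
        if not _span_length_ok(s, m.diffs):
            bad(
                "spans",
                f"span {s.lrg_start}-{s.lrg_end}: LRG length does not equal "
                "assembly length after accounting for insertion/deletion diffs",
            )
    for d in m.diffs:
        if d.kind == "mismatch":
            if not d.lrg_allele or len(d.lrg_allele) != len(d.other_allele):
                out.append(
                    Violation(
                        "SequenceDiff",
                        "kind",
                        "mismatch requires equal-length non-empty alleles",
                    )
                )
            elif genome[d.lrg_start - 1 : d.lrg_end] != d.lrg_allele:
                out.append(
                    Violation(
                        "SequenceDiff",
                        "lrg_allele",
                        f"mismatch allele at {d.lrg_start} disagrees with the "
                        "genomic sequence",
                    )
                )
        elif d.kind == "lrg_insertion":
            if d.other_allele:
                out.append(
                    Violation(
                        "SequenceDiff", "other_allele",
                        "lrg_insertion must have an empty assembly allele",
                    )
                )
        elif d.kind == "assembly_insertion":
            if d.lrg_allele:
                out.append(
                    Violation(
                        "SequenceDiff", "lrg_allele",
                        "assembly_insertion must have an empty LRG allele",
                    )
                )
        else:
            out.append(Violation("SequenceDiff", "kind", f"unknown kind {d.kind!r}"))


def validate_record(record: LrgRecord) -> list[Violation]:
    """Check every internal-consistency rule of the record.

    Returns an empty list when the record is fully consistent. Violations are
    data, never exceptions: each names the type, field and rule broken, with
    a severity of ``error`` or (for permitted-but-unusual states such as a
    fixed section with no transcripts) ``warning``.
    """
    out: list[Violation] = []
    if not LRG_ID_RE.match(record.lrg_id):
        out.append(
            Violation(
                "LrgRecord",
                "lrg_id",
                f"{record.lrg_id!r} does not match 'LRG_[number]' "
                "(no version suffix permitted)",
            )
        )
    if record.status not in ("pending", "public"):
        out.append(
            Violation("LrgRecord", "status", f"unknown status {record.status!r}")
        )

    fixed = record.fixed
    genome = fixed.genomic_sequence
    if len(genome) < 1:
        out.append(
            Violation("FixedSection", "genomic_sequence", "empty genomic sequence")
        )
    elif not _DNA_RE.match(genome):
        out.append(
            Violation(
                "FixedSection",
                "genomic_sequence",
                "sequence contains characters outside A/C/G/T/N (uppercase)",
            )
        )
    if not fixed.transcripts:
        out.append(
            Violation(
                "FixedSection",
                "transcripts",
                "fixed section has no transcripts (permitted for non-genic loci)",
                severity="warning",
            )
        )
    for i, t in enumerate(fixed.transcripts, start=1):
        _check_transcript(t, i, genome, out)
    _check_numbering(fixed, out)

    upd = record.updatable
    seen = set()
    for m in upd.mappings:
        if m.assembly in seen:
            out.append(
                Violation(
                    "UpdatableSection",
                    "mappings",
                    f"more than one mapping for assembly {m.assembly!r}",
                )
            )
        seen.add(m.assembly)
        _check_mapping(m, genome, out)
    names = {t.name for t in fixed.transcripts}
    for a in upd.annotation_sets:
        if a.source not in ANNOTATION_SOURCES:
            out.append(
                Violation("AnnotationSet", "source", f"unknown source {a.source!r}")
            )
        unknown = set(a.fixed_transcript_marks) - names
        if unknown:
            out.append(
                Violation(
                    "AnnotationSet",
                    "fixed_transcript_marks",
                    f"marks reference unknown fixed transcripts: {sorted(unknown)}",
                )
            )
    assigned = set(fixed.numbering.labels.values())
    for leg in upd.legacy_numberings:
        unknown = set(leg.exon_map) - assigned
        if unknown:
            out.append(
                Violation(
                    "LegacyNumbering",
                    "exon_map",
                    f"keys not among assigned LRG labels: {sorted(unknown)}",
                )
            )
    return out


# ---------------------------------------------------------------------------
# record-level operations


def replace_updatable(record: LrgRecord, new_updatable: UpdatableSection) -> LrgRecord:
    """Swap in a fresh updatable section; the fixed section is untouched.

    Raises ``ValueError`` if the new section's fixed-transcript marks name
    transcripts the fixed section does not have.
    """
    names = {t.name for t in record.fixed.transcripts}
    for a in new_updatable.annotation_sets:
        unknown = set(a.fixed_transcript_marks) - names
        if unknown:
            raise ValueError(
                f"annotation set {a.source!r} marks unknown fixed transcripts: "
                f"{sorted(unknown)}"
            )
    return replace(record, updatable=new_updatable)


def mark_superseded(record: LrgRecord, successor_id: str, note: str = "") -> LrgRecord:
    """Annotate a record as superseded by a new accession.

    The fixed section never changes — even to correct an error — so a
    problematic record is flagged here and a successor record with an
    independent accession carries the corrected sequence.
    """
    if not LRG_ID_RE.match(successor_id):
        raise ValueError(
            f"malformed successor accession {successor_id!r}: expected "
            "'LRG_[number]' with no version suffix (accessions are never versioned)"
        )
    if successor_id == record.lrg_id:
        raise ValueError("a record cannot be superseded by itself")
    text = f"superseded_by {successor_id}"
    if note:
        text += f": {note}"
    upd = record.updatable
    return replace(record, updatable=replace(upd, notes=upd.notes + (text,)))
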