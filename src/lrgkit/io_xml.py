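"""Read and write records as single XML files; export sequences as FASTA.

The dialect (documented in ``docs/schema.md``) mirrors the record's content
tree: an ``<lrg>`` root carrying ``schema_version``, the accession and
status, a ``<fixed_annotation>`` with sequences / transcripts / exon
numbering, and an ``<updatable_annotation>`` with mappings, annotation sets,
legacy numbering and notes. Unrecognized children of the updatable section
are preserved verbatim in an opaque extras store, so files from richer
dialects survive a read/write round trip.

Output is deterministic: identical documents serialize to identical bytes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import IO, Union

from lxml import etree

from .model import (
    AnnotatedTranscript,
    AnnotationSet,
    AssemblyMapping,
    ExonNumbering,
    ExonSpan,
    FixedProtein,
    FixedSection,
    FixedTranscript,
    GeneAnnotation,
    LegacyNumbering,
    LrgRecord,
    MappingSpan,
    SequenceDiff,
    UpdatableSection,
    validate_record,
)

__all__ = [
    "LrgDocument",
    "LrgParseError",
    "LrgValidationError",
    "read_lrg",
    "write_lrg",
    "export_fasta",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "0.1"

_KNOWN_UPDATABLE = {"mapping", "annotation_set", "legacy_numbering", "note"}


class LrgParseError(ValueError):
    """The file is not a readable record (malformed XML, missing mandatory
    elements, or non-numeric coordinate fields)."""


class LrgValidationError(ValueError):
    def __init__(self, violations):
        self.violations = list(violations)
        lines = "\n".join(f"  {v}" for v in self.violations)
        super().__init__(f"record fails validation:\n{lines}")


@dataclass(frozen=True)
class LrgDocument:
    """A record plus the schema version of the file that carries it."""

    record: LrgRecord
    schema_version: str = SCHEMA_VERSION


Source = Union[str, "io.IOBase", IO]


# ---------------------------------------------------------------------------
# reading


def _req(parent: etree._Element, tag: str) -> etree._Element:
    el = parent.find(tag)
    if el is None:
        raise LrgParseError(f"mandatory element <{tag}> missing under <{parent.tag}>")
    return el


def _int_attr(el: etree._Element, name: str) -> int:
    raw = el.get(name)
    if raw is None:
        raise LrgParseError(f"<{el.tag}> missing attribute {name!r}")
    try:
        return int(raw)
    except ValueError:
        raise LrgParseError(
            f"<{el.tag}> attribute {name!r} is non-numeric: {raw!r}"
        ) from None


def _text(el: etree._Element) -> str:
    return (el.text or "").strip()


def _parse_transcript(el: etree._Element) -> FixedTranscript:
    name = el.get("name") or ""
    exons = tuple(
        ExonSpan(_int_attr(e, "start"), _int_attr(e, "end"))
        for e in el.findall("exon")
    )
    cdna = _text(_req(el, "cdna")).upper()
    coding = None
    cr = el.find("coding_region")
    if cr is not None:
        coding = (_int_attr(cr, "start"), _int_attr(cr, "end"))
    protein = None
    pr = el.find("protein")
    if pr is not None:
        protein = FixedProtein(pr.get("name") or "", _text(pr).upper())
    return FixedTranscript(name, exons, cdna, coding, protein)


def _parse_numbering(el: etree._Element) -> ExonNumbering:
    labels = {}
    for e in el.findall("exon"):
        labels[(_int_attr(e, "start"), _int_attr(e, "end"))] = _int_attr(e, "label")
    per = {}
    for t in el.findall("transcript"):
        raw = t.get("labels", "")
        per[t.get("name") or ""] = (
            tuple(int(x) for x in raw.split(",")) if raw else ()
        )
    return ExonNumbering(labels=labels, per_transcript=per)


def _parse_mapping(el: etree._Element) -> AssemblyMapping:
    spans = tuple(
        MappingSpan(
            _int_attr(s, "lrg_start"),
            _int_attr(s, "lrg_end"),
            _int_attr(s, "other_start"),
            _int_attr(s, "other_end"),
            _int_attr(s, "strand"),
        )
        for s in el.findall("span")
    )
    diffs = tuple(
        SequenceDiff(
            d.get("kind") or "",
            _int_attr(d, "lrg_start"),
            _int_attr(d, "lrg_end"),
            _int_attr(d, "other_start"),
            _int_attr(d, "other_end"),
            d.get("lrg_allele", ""),
            d.get("other_allele", ""),
        )
        for d in el.findall("diff")
    )
    return AssemblyMapping(
        assembly=el.get("assembly") or "",
        other_name=el.get("other_name") or "",
        spans=spans,
        diffs=diffs,
    )


def _parse_annotation_set(el: etree._Element) -> AnnotationSet:
    genes = []
    for g in el.findall("gene"):
        genes.append(
            GeneAnnotation(
                symbol=g.get("symbol") or "",
                start=_int_attr(g, "start"),
                end=_int_attr(g, "end"),
                partial=g.get("partial") == "true",
                synonyms=tuple(_text(s) for s in g.findall("synonym")),
                xrefs=tuple(
                    (x.get("db") or "", x.get("id") or "")
                    for x in g.findall("xref")
                ),
                transcripts=tuple(
                    AnnotatedTranscript(
                        t.get("name") or "",
                        tuple(
                            ExonSpan(_int_attr(e, "start"), _int_attr(e, "end"))
                            for e in t.findall("exon")
                        ),
                    )
                    for t in g.findall("transcript")
                ),
            )
        )
    marks = tuple(
        m.get("name") or "" for m in el.findall("fixed_transcript_mark")
    )
    return AnnotationSet(
        source=el.get("source") or "",
        genes=tuple(genes),
        fixed_transcript_marks=marks,
    )


def _parse_legacy(el: etree._Element) -> LegacyNumbering:
    emap = {
        _int_attr(e, "lrg_label"): e.get("legacy_label") or ""
        for e in el.findall("exon")
    }
    aa = el.get("aa_offset")
    return LegacyNumbering(
        name=el.get("name") or "",
        exon_map=emap,
        aa_offset=int(aa) if aa is not None else None,
    )


def read_lrg(source: Source) -> LrgDocument:
    """Parse a record file (path or stream) into an :class:`LrgDocument`.

    Raises :class:`LrgParseError` for malformed XML, a missing mandatory
    element (accession, genomic sequence, ...) or non-numeric coordinates.
    """
    try:
        tree = etree.parse(source)
    except (etree.XMLSyntaxError, OSError) as exc:
        raise LrgParseError(f"cannot parse XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != "lrg":
        raise LrgParseError(f"root element is <{root.tag}>, expected <lrg>")
    schema_version = root.get("schema_version") or SCHEMA_VERSION

    lrg_id = _text(_req(root, "id"))
    if not lrg_id:
        raise LrgParseError("mandatory element <id> is empty")
    status = _text(_req(root, "status"))

    fx = _req(root, "fixed_annotation")
    seq_el = _req(fx, "sequence")
    fixed = FixedSection(
        hgnc_symbol=_text(_req(fx, "hgnc_symbol")),
        requesters=tuple(_text(s) for s in fx.findall("source")),
        genomic_sequence=_text(seq_el).upper(),
        transcripts=tuple(_parse_transcript(t) for t in fx.findall("transcript")),
        numbering=_parse_numbering(_req(fx, "exon_numbering")),
    )

    upd_el = root.find("updatable_annotation")
    mappings, ann_sets, legacies, notes, extras = [], [], [], [], []
    if upd_el is not None:
        for child in upd_el:
            if not isinstance(child.tag, str):
                continue  # comments
            if child.tag == "mapping":
                mappings.append(_parse_mapping(child))
            elif child.tag == "annotation_set":
                ann_sets.append(_parse_annotation_set(child))
            elif child.tag == "legacy_numbering":
                legacies.append(_parse_legacy(child))
            elif child.tag == "note":
                notes.append(_text(child))
            else:
                extras.append(
                    etree.tostring(child, encoding="unicode").strip()
                )
    record = LrgRecord(
        lrg_id=lrg_id,
        status=status,
        fixed=fixed,
        updatable=UpdatableSection(
            mappings=tuple(mappings),
            annotation_sets=tuple(ann_sets),
            legacy_numberings=tuple(legacies),
            notes=tuple(notes),
            extras=tuple(extras),
        ),
    )
    return LrgDocument(record=record, schema_version=schema_version)


# ---------------------------------------------------------------------------
# writing


def _sub(parent, tag, text=None, **attrs):
    el = etree.SubElement(
        parent, tag, {k: str(v) for k, v in attrs.items() if v is not None}
    )
    if text is not None:
        el.text = str(text)
    return el


def _build_tree(doc: LrgDocument) -> etree._Element:
    rec = doc.record
    root = etree.Element("lrg", schema_version=doc.schema_version)
    _sub(root, "id", rec.lrg_id)
    _sub(root, "status", rec.status)

    fx = _sub(root, "fixed_annotation")
    _sub(fx, "hgnc_symbol", rec.fixed.hgnc_symbol)
    for r in rec.fixed.requesters:
        _sub(fx, "source", r)
    _sub(fx, "sequence", rec.fixed.genomic_sequence)
    for t in rec.fixed.transcripts:
        tel = _sub(fx, "transcript", name=t.name)
        for ex in t.exons:
            _sub(tel, "exon", start=ex.start, end=ex.end)
        _sub(tel, "cdna", t.cdna_sequence)
        if t.coding_region is not None:
            _sub(tel, "coding_region", start=t.coding_region[0], end=t.coding_region[1])
        if t.protein is not None:
            _sub(tel, "protein", t.protein.sequence, name=t.protein.name)
    num = _sub(fx, "exon_numbering")
    for (s, e), lab in sorted(rec.fixed.numbering.labels.items(), key=lambda kv: kv[1]):
        _sub(num, "exon", start=s, end=e, label=lab)
    fixed_order = [t.name for t in rec.fixed.transcripts]
    names = fixed_order + sorted(
        set(rec.fixed.numbering.per_transcript) - set(fixed_order)
    )
    for name in names:
        if name in rec.fixed.numbering.per_transcript:
            labs = ",".join(str(x) for x in rec.fixed.numbering.per_transcript[name])
            _sub(num, "transcript", name=name, labels=labs)

    upd = _sub(root, "updatable_annotation")
    for m in rec.updatable.mappings:
        mel = _sub(upd, "mapping", assembly=m.assembly, other_name=m.other_name)
        for s in m.spans:
            _sub(
                mel, "span",
                lrg_start=s.lrg_start, lrg_end=s.lrg_end,
                other_start=s.other_start, other_end=s.other_end,
                strand=s.strand,
            )
        for d in m.diffs:
            _sub(
                mel, "diff",
                kind=d.kind,
                lrg_start=d.lrg_start, lrg_end=d.lrg_end,
                other_start=d.other_start, other_end=d.other_end,
                lrg_allele=d.lrg_allele, other_allele=d.other_allele,
            )
    for a in rec.updatable.annotation_sets:
        ael = _sub(upd, "annotation_set", source=a.source)
        for g in a.genes:
            gel = _sub(
                ael, "gene",
                symbol=g.symbol, start=g.start, end=g.end,
                partial="true" if g.partial else "false",
            )
            for s in g.synonyms:
                _sub(gel, "synonym", s)
            for db, ident in g.xrefs:
                _sub(gel, "xref", db=db, id=ident)
            for t in g.transcripts:
                tel = _sub(gel, "transcript", name=t.name)
                for ex in t.exons:
                    _sub(tel, "exon", start=ex.start, end=ex.end)
        for mname in a.fixed_transcript_marks:
            _sub(ael, "fixed_transcript_mark", name=mname)
    for leg in rec.updatable.legacy_numberings:
        lel = _sub(upd, "legacy_numbering", name=leg.name, aa_offset=leg.aa_offset)
        for lab in sorted(leg.exon_map):
            _sub(lel, "exon", lrg_label=lab, legacy_label=leg.exon_map[lab])
    for note in rec.updatable.notes:
        _sub(upd, "note", note)
    for raw in rec.updatable.extras:
        upd.append(etree.fromstring(raw))
    return root


def write_lrg(doc: LrgDocument, dest: Source, *, force: bool = False) -> None:
    """Serialize a document to a path or binary stream.

    Refuses to write a record with error-severity validation violations
    unless ``force`` is set (a warning is logged instead). Output is
    byte-identical for identical input.
    """
    violations = [
        v for v in validate_record(doc.record) if v.severity == "error"
    ]
    if violations:
        if not force:
            raise LrgValidationError(violations)
        import logging

        logging.getLogger("lrgkit").warning(
            "writing record with %d validation violations (force=True)",
            len(violations),
        )
    data = etree.tostring(
        _build_tree(doc), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )
    if hasattr(dest, "write"):
        dest.write(data)
    else:
        with open(dest, "wb") as fh:
            fh.write(data)


# ---------------------------------------------------------------------------
# FASTA export


def export_fasta(record: LrgRecord, selector: str = "genomic") -> str:
    """Single-record FASTA for one sequence of the record.

    ``selector`` is ``genomic``, a transcript name (``t1`` -> cDNA) or a
    protein name (``p1``). Headers are ``>LRG_1`` for the genomic sequence
    and ``>LRG_1t1`` / ``>LRG_1p1`` otherwise; sequence lines wrap at 60
    columns.
    """
    if selector == "genomic":
        header = record.lrg_id
        seq = record.fixed.genomic_sequence
    else:
        found = None
        for t in record.fixed.transcripts:
            if t.name == selector:
                found = t.cdna_sequence
            elif t.protein is not None and t.protein.name == selector:
                found = t.protein.sequence
        if found is None:
            raise ValueError(
                f"unknown selector {selector!r}: expected 'genomic', a "
                "transcript name like 't1' or a protein name like 'p1'"
            )
        header = f"{record.lrg_id}{selector}"
        seq = found
    lines = [f">{header}"]
    lines.extend(seq[i : i + 60] for i in range(0, len(seq), 60))
    return "\n".join(lines) + "\n"
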