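"""Locus-specific stable exon numbering.

Exons of all transcripts in the fixed section are numbered consecutively
5'-3' by genomic location, and the numbering is then projected onto each
transcript. Two exons are "the same exon" exactly when their (start, end)
spans are identical; overlapping-but-unequal exons get distinct labels, since
merging biologically different boundaries is never safe.

Once a record is public the numbering is frozen: a transcript added later
never changes existing labels — its novel exons receive the next unused
integers in 5'-3' order (or community-decreed labels via an override map).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

import pandas as pd

from .model import ExonNumbering, ExonSpan, FixedTranscript, LrgRecord

__all__ = ["assign_exon_numbers", "extend_numbering", "exon_table"]


def assign_exon_numbers(transcripts: Iterable[FixedTranscript]) -> ExonNumbering:
    """Number the union of all transcripts' distinct exons 1..K, 5'-3'.

    Spans are ordered by genomic start, ties broken by end (shorter exon
    first). Each transcript's row is the projection of the global labels onto
    its own exon list, so labels within one transcript strictly increase.
    """
    transcripts = list(transcripts)
    if not transcripts:
        raise ValueError("at least one transcript is required")
    spans = sorted({(e.start, e.end) for t in transcripts for e in t.exons})
    labels = {span: i for i, span in enumerate(spans, start=1)}
    per_transcript = {
        t.name: tuple(labels[(e.start, e.end)] for e in t.exons) for t in transcripts
    }
    return ExonNumbering(labels=labels, per_transcript=per_transcript)


def extend_numbering(
    existing: ExonNumbering,
    new_transcript: FixedTranscript,
    override: Optional[Mapping[tuple[int, int], int]] = None,
) -> ExonNumbering:
    """Add a transcript without disturbing any existing label.

    Spans already labeled keep their labels exactly. Each novel span receives
    the next unused integer, novel spans taken in 5'-3' (start, end) order.
    ``override`` maps a novel (start, end) span to a community-decreed label
    instead; overrides may not collide with existing or other new labels.
    Returns a new :class:`~lrgkit.model.ExonNumbering`; the input is untouched.
    """
    override = dict(override or {})
    labels = dict(existing.labels)
    used = set(labels.values())
    for span, lab in override.items():
        if span in labels and labels[span] != lab:
            raise ValueError(f"override for {span} conflicts with existing label")
        if span not in labels and lab in used:
            raise ValueError(f"override label {lab} already in use")

    novel = sorted(
        {
            (e.start, e.end)
            for e in new_transcript.exons
            if (e.start, e.end) not in labels
        }
    )
    nxt = max(used, default=0) + 1
    for span in novel:
        if span in override:
            labels[span] = override[span]
            used.add(override[span])
        else:
            while nxt in used:
                nxt += 1
            labels[span] = nxt
            used.add(nxt)
            nxt += 1

    per_transcript = dict(existing.per_transcript)
    per_transcript[new_transcript.name] = tuple(
        labels[(e.start, e.end)] for e in new_transcript.exons
    )
    return ExonNumbering(labels=labels, per_transcript=per_transcript)


def exon_table(record: LrgRecord) -> pd.DataFrame:
    """One row per (transcript, exon): stable label, genomic span, cDNA span,
    and any legacy labels carried in the updatable section.

    Legacy columns are named ``legacy_<scheme>``; cells are empty where a
    scheme provides no label for that exon. cDNA spans start at 1 for the
    first exonic base and are contiguous per transcript.
    """
    legacy = {l.name: l.exon_map for l in record.updatable.legacy_numberings}
    rows = []
    for t in record.fixed.transcripts:
        cpos = 1
        for ex in t.exons:
            lab = record.fixed.numbering.labels[(ex.start, ex.end)]
            row = {
                "transcript": t.name,
                "exon_label": lab,
                "lrg_start": ex.start,
                "lrg_end": ex.end,
                "cdna_start": cpos,
                "cdna_end": cpos + ex.length - 1,
            }
            for name, emap in legacy.items():
                row[f"legacy_{name}"] = emap.get(lab, "")
            rows.append(row)
            cpos += ex.length
    cols = ["transcript", "exon_label", "lrg_start", "lrg_end", "cdna_start", "cdna_end"]
    cols += [f"legacy_{name}" for name in legacy]
    return pd.DataFrame(rows, columns=cols)
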