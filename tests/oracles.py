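"""Brute-force reference implementations used only as test oracles.

Each works by explicit enumeration — materializing every base or alignment
column — independently of the arithmetic in the package, so agreement is a
meaningful check rather than a tautology.
"""

import random

from lrgkit import AssemblyMapping, MappingSpan, SequenceDiff


def scan_c_coordinates(transcript, seq_len):
    """Expected c. rendering for every genomic position 1..seq_len.

    Walks the sequence base by base: exonic bases take their cDNA index and
    are classified against the CDS bounds; intronic bases pick the nearer
    exon boundary by explicit distance comparison (ties to the upstream
    side); positions beyond the transcript continue the UTR counts.
    """
    cs, ce = transcript.coding_region
    cdna_of = {}
    d = 0
    for ex in transcript.exons:
        for g in range(ex.start, ex.end + 1):
            d += 1
            cdna_of[g] = d
    cdna_len = d

    def render_exonic(d):
        if d < cs:
            return f"-{cs - d}"
        if d > ce:
            return f"*{d - ce}"
        return str(d - cs + 1)

    first = transcript.exons[0].start
    last = transcript.exons[-1].end
    out = {}
    for g in range(1, seq_len + 1):
        if g in cdna_of:
            out[g] = render_exonic(cdna_of[g])
        elif g < first:
            out[g] = f"-{(cs - 1) + (first - g)}"
        elif g > last:
            out[g] = f"*{(cdna_len - ce) + (g - last)}"
        else:
            prev = max(e.end for e in transcript.exons if e.end < g)
            nxt = min(e.start for e in transcript.exons if e.start > g)
            up, down = g - prev, nxt - g
            if up <= down:  # nearer upstream boundary; exact tie goes upstream
                out[g] = f"{render_exonic(cdna_of[prev])}+{up}"
            else:
                out[g] = f"{render_exonic(cdna_of[nxt])}-{down}"
    return out


def align_columns(mapping):
    """Materialize the full base-to-base alignment of a mapping.

    Returns a list of (lrg_pos | None, assembly_pos | None) pairs, one per
    alignment column, covering every span. Gap regions between spans are not
    represented (they have no columns).
    """
    columns = []
    for span in mapping.spans:
        diffs = sorted(
            (d for d in mapping.diffs
             if span.lrg_start <= d.lrg_start <= span.lrg_end),
            key=lambda d: d.lrg_start,
        )
        span_cols = []  # (lrg or None, takes_assembly_base: bool)
        lrg_ins = {}
        asm_ins_after = {}
        for d in diffs:
            if d.kind == "lrg_insertion":
                for p in range(d.lrg_start, d.lrg_end + 1):
                    lrg_ins[p] = True
            elif d.kind == "assembly_insertion":
                asm_ins_after[d.lrg_start] = len(d.other_allele)
        for g in range(span.lrg_start, span.lrg_end + 1):
            if g in lrg_ins:
                span_cols.append((g, False))
            else:
                span_cols.append((g, True))
            for _ in range(asm_ins_after.get(g, 0)):
                span_cols.append((None, True))
        n_asm = sum(1 for _, takes in span_cols if takes)
        if span.strand >= 0:
            asm_positions = iter(range(span.other_start, span.other_start + n_asm))
        else:
            asm_positions = iter(
                range(span.other_end, span.other_end - n_asm, -1)
            )
        for lrg_pos, takes in span_cols:
            columns.append((lrg_pos, next(asm_positions) if takes else None))
    return columns


def random_mapping(rng: random.Random) -> AssemblyMapping:
    """A random multi-span, diff-bearing mapping with consistent lengths."""
    strand = rng.choice((1, -1))
    n_spans = rng.randint(1, 3)
    spans, all_diffs = [], []
    lrg_cursor = rng.randint(1, 5)
    other_blocks = []
    for _ in range(n_spans):
        lrg_len = rng.randint(15, 60)
        lrg_start = lrg_cursor
        lrg_end = lrg_start + lrg_len - 1
        # diffs at well-separated interior positions
        positions = sorted(
            rng.sample(range(lrg_start + 2, lrg_end - 2), k=min(rng.randint(0, 3), lrg_end - lrg_start - 4))
            if lrg_end - lrg_start > 8 else []
        )
        positions = [p for i, p in enumerate(positions)
                     if i == 0 or p - positions[i - 1] > 4]
        diffs = []
        ins_lrg = ins_other = 0
        for p in positions:
            kind = rng.choice(("mismatch", "lrg_insertion", "assembly_insertion"))
            if kind == "mismatch":
                diffs.append(SequenceDiff("mismatch", p, p, 0, 0, "A", "G"))
            elif kind == "lrg_insertion":
                ln = rng.randint(1, 3)
                diffs.append(SequenceDiff("lrg_insertion", p, p + ln - 1, 0, 0, "A" * ln, ""))
                ins_lrg += ln
            else:
                ln = rng.randint(1, 3)
                diffs.append(SequenceDiff("assembly_insertion", p, p, 0, 0, "", "C" * ln))
                ins_other += ln
        other_len = lrg_len - ins_lrg + ins_other
        spans.append((lrg_start, lrg_end, other_len))
        all_diffs.extend(diffs)
        other_blocks.append(other_len)
        lrg_cursor = lrg_end + 1 + rng.randint(1, 10)  # inter-span gap
    # assign assembly coordinates: ascending blocks for +, descending for -
    built = []
    if strand == 1:
        cursor = rng.randint(1, 100)
        for (ls, le, olen) in spans:
            built.append(MappingSpan(ls, le, cursor, cursor + olen - 1, 1))
            cursor += olen + rng.randint(1, 10)
    else:
        cursor = rng.randint(300, 400)
        for (ls, le, olen) in spans:
            built.append(MappingSpan(ls, le, cursor - olen + 1, cursor, -1))
            cursor -= olen + rng.randint(1, 10)
    return AssemblyMapping("ASM1", "chrT", tuple(built), tuple(all_diffs))


def union_sort_numbering(transcripts):
    """Numbering by literally collecting, deduplicating and sorting spans."""
    seen = []
    for t in transcripts:
        for e in t.exons:
            if (e.start, e.end) not in seen:
                seen.append((e.start, e.end))
    ordered = sorted(seen, key=lambda se: (se[0], se[1]))
    labels = {}
    for i, span in enumerate(ordered):
        labels[span] = i + 1
    per = {t.name: tuple(labels[(e.start, e.end)] for e in t.exons)
           for t in transcripts}
    return labels, per
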