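"""Construct LRG-style records from a genome slice plus a gene model.

The genomic reference of a record is the source-genome slice extending (by
default) 5 kb upstream of the first exon and 2 kb downstream of the last exon
of the requested transcripts, clipped at contig edges with a warning. The
``flank_up``/``flank_down`` parameters also cover the "however much is needed
for promoters and other regulatory elements" case — there is no promoter
detection here, callers simply widen the flank.

Minus-strand genes are stored 5'->3' on the LRG sequence (the transcription
strand), with strand -1 recorded in the assembly mapping; this makes all
transcript-level coordinate arithmetic strand-free inside the record.

:func:`make_fixture` generates seeded synthetic genomes and gene models so
that the whole pipeline can be exercised without any external data.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .exon_numbering import assign_exon_numbers
from .model import (
    AssemblyMapping,
    ExonSpan,
    FixedProtein,
    FixedSection,
    FixedTranscript,
    LrgRecord,
    MappingSpan,
    UpdatableSection,
    translate_cds,
)

__all__ = ["GeneModel", "FixtureSpec", "BuildError", "FixtureError",
           "build_record", "make_fixture", "read_gene_model"]

log = logging.getLogger("lrgkit")

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class BuildError(ValueError):
    """The gene model cannot yield a consistent record."""


class FixtureError(ValueError):
    """The fixture specification is infeasible."""


@dataclass(frozen=True)
class GeneModel:
    """A gene's structure in source-genome coordinates (1-based inclusive).

    ``requested_transcripts`` are the transcripts the community wants in the
    fixed section, each an ordered tuple of indices into ``exons``. An empty
    tuple means a single transcript using every exon.
    """

    symbol: str
    chrom: str
    strand: int  # +1 or -1
    exons: tuple[ExonSpan, ...]
    cds: Optional[tuple[int, int]] = None  # genomic span of the coding region
    requested_transcripts: tuple[tuple[int, ...], ...] = ()

    def validate(self) -> None:
        if self.strand not in (1, -1):
            raise BuildError(f"strand must be +1 or -1, got {self.strand}")
        prev = 0
        for ex in self.exons:
            if ex.start > ex.end or ex.start <= prev:
                raise BuildError(f"exons not ascending/non-overlapping at {ex}")
            prev = ex.end
        for tx in self.requested_transcripts:
            if list(tx) != sorted(set(tx)) or not tx:
                raise BuildError(f"transcript exon indices invalid: {tx}")
            if max(tx) >= len(self.exons):
                raise BuildError(f"transcript references missing exon: {tx}")
        if self.cds is not None:
            cs, ce = self.cds
            if not any(e.contains(cs) for e in self.exons) or not any(
                e.contains(ce) for e in self.exons
            ):
                raise BuildError("CDS boundaries must be exonic")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic genome + gene model.

    Defaults describe a small but structurally complete locus: a ~20 kb
    contig leaving room for the standard 5 kb / 2 kb flanks, a handful of
    exons of typical human exon size (~90-240 bp) separated by short introns,
    one coding transcript using every exon and one non-coding exon-subset
    transcript, at balanced GC. ``strand`` of 0 means choose randomly.
    """

    seed: int = 0
    genome_length: int = 20_000
    n_exons: int = 4
    exon_length_range: tuple[int, int] = (90, 240)
    intron_length_range: tuple[int, int] = (80, 600)
    strand: int = 0
    n_transcripts: int = 2
    gc_content: float = 0.5

    def validate(self) -> None:
        if self.genome_length < 1 or self.n_exons < 1 or self.n_transcripts < 1:
            raise FixtureError("counts and lengths must be positive")
        for lo, hi in (self.exon_length_range, self.intron_length_range):
            if lo < 1 or hi < lo:
                raise FixtureError("length ranges must be positive and ordered")
        if not 0.0 <= self.gc_content <= 1.0:
            raise FixtureError("gc_content must lie in [0, 1]")
        if self.strand not in (0, 1, -1):
            raise FixtureError("strand must be +1, -1 or 0 (random)")


def build_record(
    genome: str,
    model: GeneModel,
    *,
    flank_up: int = 5000,
    flank_down: int = 2000,
    lrg_number: int = 1,
    assembly: str = "GRCh38",
    status: str = "pending",
    requesters: Sequence[str] = (),
) -> LrgRecord:
    """Build a record from a source genome and gene model.

    The LRG genomic sequence is the genome slice covering the union of the
    requested transcripts' exons plus the flanks (measured on the
    transcription strand), reverse-complemented for minus-strand genes. Exon
    coordinates are re-expressed on the LRG sequence, the cDNA / coding
    region / protein are derived per transcript, exon numbering is assigned,
    and an assembly mapping back to the source genome (one span, diff-free)
    goes into the updatable section.

    A requested transcript receives a coding region only when it contains
    every model exon overlapping the CDS span; otherwise it is emitted
    non-coding.
    """
    model.validate()
    if flank_up < 0 or flank_down < 0:
        raise BuildError("flanks must be non-negative")
    genome = genome.upper()
    requested = model.requested_transcripts or (tuple(range(len(model.exons))),)
    used = sorted({i for tx in requested for i in tx})
    for i in used:
        ex = model.exons[i]
        if ex.start < 1 or ex.end > len(genome):
            raise BuildError(f"exon {ex.start}-{ex.end} outside the genome")
    first = min(model.exons[i].start for i in used)
    last = max(model.exons[i].end for i in used)

    if model.strand == 1:
        want_start, want_end = first - flank_up, last + flank_down
    else:  # upstream is the high-coordinate side on the minus strand
        want_start, want_end = first - flank_down, last + flank_up
    gs, ge = max(1, want_start), min(len(genome), want_end)
    if gs != want_start or ge != want_end:
        log.warning(
            "flanks clipped at genome edges: requested %d-%d, using %d-%d",
            want_start, want_end, gs, ge,
        )
    seq = genome[gs - 1 : ge]
    if model.strand == -1:
        seq = _revcomp(seq)

    def g2l(p: int) -> int:
        return p - gs + 1 if model.strand == 1 else ge - p + 1

    cds_exon_idx = set()
    if model.cds is not None:
        cs_g, ce_g = model.cds
        cds_exon_idx = {
            i
            for i, ex in enumerate(model.exons)
            if ex.start <= ce_g and ex.end >= cs_g
        }

    transcripts = []
    for k, tx in enumerate(requested, start=1):
        lrg_exons = tuple(
            sorted(
                (
                    ExonSpan(*sorted((g2l(model.exons[i].start), g2l(model.exons[i].end))))
                    for i in tx
                ),
                key=lambda e: e.start,
            )
        )
        cdna = "".join(seq[e.start - 1 : e.end] for e in lrg_exons)
        coding = None
        protein = None
        if model.cds is not None and cds_exon_idx <= set(tx):
            cs_g, ce_g = model.cds
            # on the minus strand the genomic CDS end is the 5' end
            l5 = g2l(cs_g if model.strand == 1 else ce_g)
            l3 = g2l(ce_g if model.strand == 1 else cs_g)
            tr = FixedTranscript(f"t{k}", lrg_exons, cdna)
            c5 = _exonic_pos(tr, l5)
            c3 = _exonic_pos(tr, l3)
            if c5 is None or c3 is None:
                raise BuildError("CDS boundary not exonic on the LRG sequence")
            coding = (c5, c3)
            cds_seq = cdna[c5 - 1 : c3]
            if len(cds_seq) % 3 != 0:
                raise BuildError(
                    f"t{k}: CDS length {len(cds_seq)} not divisible by 3"
                )
            aa = translate_cds(cds_seq)
            if "*" in aa[:-1]:
                raise BuildError(f"t{k}: internal stop codon in CDS")
            if not aa.endswith("*"):
                raise BuildError(f"t{k}: CDS does not end with a stop codon")
            protein = FixedProtein(f"p{k}", aa[:-1])
        transcripts.append(
            FixedTranscript(f"t{k}", lrg_exons, cdna, coding, protein)
        )

    fixed = FixedSection(
        hgnc_symbol=model.symbol,
        requesters=tuple(requesters),
        genomic_sequence=seq,
        transcripts=tuple(transcripts),
        numbering=assign_exon_numbers(transcripts),
    )
    mapping = AssemblyMapping(
        assembly=assembly,
        other_name=model.chrom,
        spans=(MappingSpan(1, len(seq), gs, ge, model.strand),),
    )
    return LrgRecord(
        lrg_id=f"LRG_{lrg_number}",
        status=status,
        fixed=fixed,
        updatable=UpdatableSection(mappings=(mapping,)),
    )


def _exonic_pos(transcript: FixedTranscript, g_pos: int) -> Optional[int]:
    offset = 0
    for ex in transcript.exons:
        if ex.contains(g_pos):
            return offset + (g_pos - ex.start) + 1
        offset += ex.length
    return None


# ---------------------------------------------------------------------------
# synthetic fixtures

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_STOP_CODONS = ["TAA", "TAG", "TGA"]


def make_fixture(spec: FixtureSpec) -> tuple[str, GeneModel]:
    """Generate a deterministic synthetic genome + gene model.

    For a given seed the output is bit-identical. The gene is placed leaving
    ~5.5 kb upstream and ~2.5 kb downstream margin when the genome allows, so
    default flanks fit without clipping. Transcript 1 uses every exon and
    carries a CDS that begins with ATG, ends with a stop codon and has no
    internal stop; further transcripts are random exon subsets (non-coding
    unless they happen to contain every CDS exon).
    """
    spec.validate()
    rng = random.Random(spec.seed)
    strand = spec.strand or rng.choice((1, -1))

    exon_lens = [
        rng.randint(*spec.exon_length_range) for _ in range(spec.n_exons)
    ]
    intron_lens = [
        rng.randint(*spec.intron_length_range) for _ in range(spec.n_exons - 1)
    ]
    total = sum(exon_lens) + sum(intron_lens)
    slack = spec.genome_length - total
    if slack < 0:
        raise FixtureError(
            f"{spec.n_exons} exons + introns need {total} bp, genome has "
            f"{spec.genome_length}"
        )
    # leave room for the default 5 kb upstream / 2 kb downstream flanks
    # (upstream is the high-coordinate side on the minus strand)
    left_margin = 5500 if strand == 1 else 2500
    right_margin = 2500 if strand == 1 else 5500
    if slack >= left_margin + right_margin:
        lo, hi = left_margin, slack - right_margin
    else:  # small genome: split what slack there is proportionally
        lo = hi = slack * left_margin // (left_margin + right_margin)
    offset = rng.randint(lo, hi)

    pool = "GC" if spec.gc_content >= 1 else "AT" if spec.gc_content <= 0 else None
    genome = [
        (rng.choice("GC") if rng.random() < spec.gc_content else rng.choice("AT"))
        if pool is None
        else rng.choice(pool)
        for _ in range(spec.genome_length)
    ]

    exons = []
    pos = offset + 1
    for i, elen in enumerate(exon_lens):
        exons.append(ExonSpan(pos, pos + elen - 1))
        pos += elen
        if i < len(intron_lens):
            pos += intron_lens[i]
    exons = tuple(exons)

    # carve a CDS into transcript 1 (all exons), in transcription order
    cdna_len = sum(exon_lens)
    utr5 = rng.randint(8, max(8, cdna_len // 5))
    avail = cdna_len - utr5 - 8
    if avail < 6:
        raise FixtureError("exons too short to hold a CDS")
    n_codons = rng.randint(2, avail // 3)
    cds_seq = (
        "ATG"
        + "".join(rng.choice(_SENSE_CODONS) for _ in range(n_codons - 2))
        + rng.choice(_STOP_CODONS)
    )

    order = exons if strand == 1 else tuple(reversed(exons))
    idxs: list[int] = []  # 0-based genomic indices in transcription order
    for ex in order:
        rng_pos = (
            range(ex.start - 1, ex.end)
            if strand == 1
            else range(ex.end - 1, ex.start - 2, -1)
        )
        idxs.extend(rng_pos)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for i, base in enumerate(cds_seq, start=utr5):
        gi = idxs[i]
        genome[gi] = base if strand == 1 else comp[base]
    g1 = idxs[utr5] + 1
    g2 = idxs[utr5 + len(cds_seq) - 1] + 1
    cds_span = (min(g1, g2), max(g1, g2))

    requested = [tuple(range(spec.n_exons))]
    for _ in range(spec.n_transcripts - 1):
        size = rng.randint(1, spec.n_exons)
        requested.append(tuple(sorted(rng.sample(range(spec.n_exons), size))))

    model = GeneModel(
        symbol=f"SYN{spec.seed}",
        chrom="ctg1",
        strand=strand,
        exons=exons,
        cds=cds_span,
        requested_transcripts=tuple(requested),
    )
    return "".join(genome), model


# ---------------------------------------------------------------------------
# gene-model input (GFF3)


def read_gene_model(gff_path: str, symbol: Optional[str] = None) -> GeneModel:
    """Read a gene model from a minimal GFF3 file.

    Required features: ``exon`` and (optionally) ``CDS`` lines whose
    ``Parent`` attribute names a transcript; an optional ``gene`` feature
    supplies the symbol via ``Name``/``ID`` (overridden by ``symbol``).
    Transcripts become exon-index subsets of the exon union, in Parent order
    of first appearance.
    """
    import gffutils

    db = gffutils.create_db(
        gff_path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    exon_spans: dict[tuple[int, int], None] = {}
    per_tx: dict[str, list[tuple[int, int]]] = {}
    strand = None
    chrom = None
    cds_lo, cds_hi = None, None
    gene_symbol = symbol
    for feat in db.all_features(order_by=("start",)):
        if feat.featuretype == "gene" and gene_symbol is None:
            gene_symbol = feat.attributes.get(
                "Name", feat.attributes.get("ID", ["gene"])
            )[0]
        if feat.featuretype not in ("exon", "CDS"):
            continue
        chrom = chrom or feat.seqid
        s = 1 if feat.strand != "-" else -1
        if strand is None:
            strand = s
        elif strand != s:
            raise BuildError("mixed strands in gene model")
        if feat.featuretype == "CDS":
            cds_lo = feat.start if cds_lo is None else min(cds_lo, feat.start)
            cds_hi = feat.end if cds_hi is None else max(cds_hi, feat.end)
            continue
        span = (feat.start, feat.end)
        exon_spans.setdefault(span, None)
        parents = feat.attributes.get("Parent", ["t1"])
        for p in parents:
            per_tx.setdefault(p, []).append(span)
    if not exon_spans:
        raise BuildError(f"no exon features found in {gff_path}")
    union = sorted(exon_spans)
    index = {span: i for i, span in enumerate(union)}
    requested = tuple(
        tuple(sorted(index[s] for s in spans)) for spans in per_tx.values()
    )
    return GeneModel(
        symbol=gene_symbol or "gene",
        chrom=chrom or "chr",
        strand=strand or 1,
        exons=tuple(ExonSpan(s, e) for s, e in union),
        cds=(cds_lo, cds_hi) if cds_lo is not None else None,
        requested_transcripts=requested,
    )
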