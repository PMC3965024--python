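"""Coordinate arithmetic between the record's coordinate systems.

Supported conversions:

* LRG genomic (g.) <-> transcript coding (c.) for coding transcripts, with
  HGVS 5'UTR (``-N``), 3'UTR (``*N``) and intronic offset (``N+k``/``N-k``)
  forms;
* LRG genomic (g.) <-> non-coding transcript (n.) for exonic positions;
* coding position -> codon/residue, and the protein consequence of a coding
  substitution;
* LRG genomic <-> assembly coordinates through the alignment spans and
  enumerated sequence differences of an :class:`~lrgkit.model.AssemblyMapping`.

Because minus-strand genes are stored 5'->3' on the LRG sequence, all of the
transcript-level arithmetic here is strand-free; strand only enters the
assembly remapping.

Intronic positions are anchored on the nearest exon boundary: offset ``k``
from the upstream boundary goes to the "+" side iff ``k <= (I+1)//2`` for an
intron of length ``I``, which assigns the exact-tie middle base of odd-length
introns to the upstream side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import AssemblyMapping, FixedTranscript, SequenceDiff, translate_cds

__all__ = [
    "CdnaCoord",
    "ProteinCoord",
    "CoordinateError",
    "OutOfRangeError",
    "NonCodingTranscriptError",
    "CodingTranscriptError",
    "RefAlleleMismatch",
    "UnmappedGapError",
    "UnmappableDiffError",
    "g_to_c",
    "c_to_g",
    "g_to_n",
    "n_to_g",
    "codon_of",
    "predict_protein_change",
    "lrg_to_assembly",
    "assembly_to_lrg",
    "AA_3LETTER",
]


class CoordinateError(ValueError):
    """Base class for coordinate-conversion failures."""


class OutOfRangeError(CoordinateError):
    """Position outside the addressable range of the target system."""


class NonCodingTranscriptError(CoordinateError):
    """c. arithmetic requested on a transcript without a coding region."""


class CodingTranscriptError(CoordinateError):
    """n. arithmetic requested on a coding transcript (use c. instead)."""


class RefAlleleMismatch(CoordinateError):
    def __init__(self, expected: str, given: str, where: str):
        self.expected = expected
        self.given = given
        super().__init__(
            f"reference allele mismatch at {where}: record has {expected!r}, "
            f"expression gives {given!r}"
        )


class UnmappedGapError(CoordinateError):
    """Position falls between alignment spans (an unaligned region)."""


class UnmappableDiffError(CoordinateError):
    """Position falls inside an insertion difference and has no counterpart."""


@dataclass(frozen=True)
class CdnaCoord:
    """An HGVS c. position: CDS base, 5'UTR (``-N``), or 3'UTR (``*N``),
    optionally with a signed intronic offset from the anchoring exonic base."""

    anchor: str  # "cds", "utr5" or "utr3"
    base: int  # positive magnitude
    offset: int = 0

    def __post_init__(self):
        if self.anchor not in ("cds", "utr5", "utr3"):
            raise ValueError(f"unknown anchor {self.anchor!r}")
        if self.base < 1:
            raise ValueError("base magnitude must be >= 1 (HGVS has no zero)")

    def __str__(self) -> str:
        if self.anchor == "utr5":
            s = f"-{self.base}"
        elif self.anchor == "utr3":
            s = f"*{self.base}"
        else:
            s = str(self.base)
        if self.offset:
            s += f"+{self.offset}" if self.offset > 0 else str(self.offset)
        return s


# 1-letter -> 3-letter amino-acid codes, built from Biopython's IUPAC data;
# the stop character renders as "Ter" per HGVS protein conventions.
from Bio.Data.IUPACData import protein_letters_1to3

AA_3LETTER = dict(protein_letters_1to3)
AA_3LETTER["*"] = "Ter"
AA_3LETTER["X"] = "Xaa"
AA_1LETTER = {v: k for k, v in AA_3LETTER.items()}


@dataclass(frozen=True)
class ProteinCoord:
    """A protein-level substitution: 1-based residue with 3-letter alleles.

    ``alt_aa == ref_aa`` marks a synonymous change (rendered ``p.Xaa123=``).
    """

    residue: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self):
        if self.residue < 1:
            raise ValueError("residue index must be >= 1")

    @property
    def synonymous(self) -> bool:
        return self.ref_aa == self.alt_aa

    def __str__(self) -> str:
        alt = "=" if self.synonymous else self.alt_aa
        return f"{self.ref_aa}{self.residue}{alt}"


# ---------------------------------------------------------------------------
# transcript-level conversions


def _exonic_cdna_pos(transcript: FixedTranscript, g_pos: int) -> Optional[int]:
    """1-based cDNA position of an exonic genomic position, else None."""
    offset = 0
    for ex in transcript.exons:
        if ex.contains(g_pos):
            return offset + (g_pos - ex.start) + 1
        offset += ex.length
    return None


def _cdna_to_c(transcript: FixedTranscript, d: int) -> CdnaCoord:
    cs, ce = transcript.coding_region
    if d < cs:
        return CdnaCoord("utr5", cs - d)
    if d > ce:
        return CdnaCoord("utr3", d - ce)
    return CdnaCoord("cds", d - cs + 1)


def g_to_c(transcript: FixedTranscript, g_pos: int) -> CdnaCoord:
    """Convert an LRG genomic position to a c. coordinate on a coding transcript.

    Exonic positions land in the 5'UTR, CDS or 3'UTR with offset 0. Intronic
    positions anchor on the nearest exon boundary with a signed offset.
    Positions upstream/downstream of the transcript continue the UTR counts
    (``-N`` / ``*N``) without intron offsets.
    """
    if transcript.coding_region is None:
        raise NonCodingTranscriptError(
            f"{transcript.name} has no coding region; use g_to_n"
        )
    if g_pos < 1:
        raise OutOfRangeError(f"genomic position {g_pos} < 1")
    first, last = transcript.span
    cs, ce = transcript.coding_region
    if g_pos < first:
        return CdnaCoord("utr5", (cs - 1) + (first - g_pos))
    if g_pos > last:
        utr3 = transcript.cdna_length - ce
        return CdnaCoord("utr3", utr3 + (g_pos - last))
    d = _exonic_cdna_pos(transcript, g_pos)
    if d is not None:
        return _cdna_to_c(transcript, d)
    # intronic: find flanking exons
    for prev, nxt in zip(transcript.exons, transcript.exons[1:]):
        if prev.end < g_pos < nxt.start:
            intron_len = nxt.start - prev.end - 1
            k = g_pos - prev.end
            if k <= (intron_len + 1) // 2:
                anchor = _cdna_to_c(transcript, _exonic_cdna_pos(transcript, prev.end))
                return CdnaCoord(anchor.anchor, anchor.base, offset=k)
            anchor = _cdna_to_c(transcript, _exonic_cdna_pos(transcript, nxt.start))
            return CdnaCoord(anchor.anchor, anchor.base, offset=-(nxt.start - g_pos))
    raise OutOfRangeError(f"position {g_pos} not addressable on {transcript.name}")


def _c_to_cdna(transcript: FixedTranscript, coord: CdnaCoord) -> int:
    """cDNA index for a c. coordinate; may fall outside [1, cdna_length] for
    positions beyond the transcript ends (handled by the caller)."""
    cs, ce = transcript.coding_region
    if coord.anchor == "utr5":
        return cs - coord.base
    if coord.anchor == "utr3":
        return ce + coord.base
    if coord.base > ce - cs + 1:
        raise OutOfRangeError(
            f"c.{coord.base} beyond the {ce - cs + 1}-base CDS of {transcript.name}"
        )
    return cs - 1 + coord.base


def _genomic_of_cdna(transcript: FixedTranscript, d: int) -> int:
    offset = 0
    for ex in transcript.exons:
        if d <= offset + ex.length:
            return ex.start + (d - offset - 1)
        offset += ex.length
    raise OutOfRangeError(f"cDNA position {d} beyond transcript")


def c_to_g(transcript: FixedTranscript, coord: CdnaCoord) -> int:
    """Exact inverse of :func:`g_to_c` on its domain."""
    if transcript.coding_region is None:
        raise NonCodingTranscriptError(
            f"{transcript.name} has no coding region; use n_to_g"
        )
    d = _c_to_cdna(transcript, coord)
    first, last = transcript.span
    if coord.offset == 0:
        if d < 1:  # upstream of the transcript, counted through the 5'UTR
            return first - (1 - d)
        if d > transcript.cdna_length:
            return last + (d - transcript.cdna_length)
        return _genomic_of_cdna(transcript, d)
    # intronic offset: anchor must be an exon boundary
    if not 1 <= d <= transcript.cdna_length:
        raise OutOfRangeError("intronic offset on a position outside the transcript")
    g_anchor = _genomic_of_cdna(transcript, d)
    g = g_anchor + coord.offset
    if coord.offset > 0:
        boundary_ends = {ex.end for ex in transcript.exons[:-1]}
        if g_anchor not in boundary_ends:
            raise OutOfRangeError(f"{coord} anchors '+' on a non-boundary base")
        nxt = min(ex.start for ex in transcript.exons if ex.start > g_anchor)
        if g >= nxt:
            raise OutOfRangeError(f"offset +{coord.offset} exceeds the intron")
    else:
        boundary_starts = {ex.start for ex in transcript.exons[1:]}
        if g_anchor not in boundary_starts:
            raise OutOfRangeError(f"{coord} anchors '-' on a non-boundary base")
        prev = max(ex.end for ex in transcript.exons if ex.end < g_anchor)
        if g <= prev:
            raise OutOfRangeError(f"offset {coord.offset} exceeds the intron")
    return g


def g_to_n(transcript: FixedTranscript, g_pos: int) -> int:
    """Non-coding (n.) position: 1-based offset within the exon concatenation.

    Only exonic positions are addressable in n. coordinates here.
    """
    if transcript.coding_region is not None:
        raise CodingTranscriptError(
            f"{transcript.name} has a coding region; use g_to_c"
        )
    d = _exonic_cdna_pos(transcript, g_pos)
    if d is None:
        raise OutOfRangeError(
            f"position {g_pos} is not exonic on {transcript.name}; "
            "intronic n. coordinates are not supported"
        )
    return d


def n_to_g(transcript: FixedTranscript, n_pos: int) -> int:
    """Inverse of :func:`g_to_n`."""
    if transcript.coding_region is not None:
        raise CodingTranscriptError(
            f"{transcript.name} has a coding region; use c_to_g"
        )
    if not 1 <= n_pos <= transcript.cdna_length:
        raise OutOfRangeError(
            f"n.{n_pos} beyond the {transcript.cdna_length}-base transcript"
        )
    return _genomic_of_cdna(transcript, n_pos)


# ---------------------------------------------------------------------------
# codons and protein consequences


def codon_of(c_base: int) -> tuple[int, int]:
    """Residue index and position-in-codon (1..3) of a CDS nucleotide.

    The residue is ``ceil(c_base / 3)``: CDS bases 1-3 form codon 1, bases
    4-6 codon 2, and so on.
    """
    if c_base < 1:
        raise OutOfRangeError("CDS positions start at 1")
    return (c_base + 2) // 3, (c_base - 1) % 3 + 1


def predict_protein_change(
    transcript: FixedTranscript, coord: CdnaCoord, ref: str, alt: str
) -> ProteinCoord:
    """Protein consequence of a single-base coding substitution.

    Mutates the affected codon, translates old and new codons with the
    standard genetic code and returns the residue with 3-letter alleles
    (stop rendered ``Ter``; a synonymous result has ``alt_aa == ref_aa``).
    """
    if transcript.coding_region is None:
        raise NonCodingTranscriptError(f"{transcript.name} has no coding region")
    if coord.anchor != "cds" or coord.offset != 0:
        raise OutOfRangeError(
            f"c.{coord} is not an exonic CDS position; no protein consequence"
        )
    cs, ce = transcript.coding_region
    cds = transcript.cdna_sequence[cs - 1 : ce]
    if coord.base > len(cds):
        raise OutOfRangeError(f"c.{coord.base} beyond the {len(cds)}-base CDS")
    if cds[coord.base - 1] != ref:
        raise RefAlleleMismatch(cds[coord.base - 1], ref, f"c.{coord.base}")
    residue, codon_pos = codon_of(coord.base)
    codon = cds[3 * (residue - 1) : 3 * residue]
    new_codon = codon[: codon_pos - 1] + alt + codon[codon_pos:]
    ref_aa = translate_cds(codon)
    alt_aa = translate_cds(new_codon)
    return ProteinCoord(residue, AA_3LETTER[ref_aa], AA_3LETTER[alt_aa])


# ---------------------------------------------------------------------------
# assembly remapping


def _span_diffs(
    mapping: AssemblyMapping, span
) -> list[SequenceDiff]:
    return sorted(
        (
            d
            for d in mapping.diffs
            if span.lrg_start <= d.lrg_start <= span.lrg_end
        ),
        key=lambda d: (d.lrg_start, d.lrg_end),
    )


def lrg_to_assembly(mapping: AssemblyMapping, g_pos: int) -> tuple[int, int]:
    """Map an LRG genomic position to (assembly position, strand).

    Insertion/deletion differences inside a span shift positions 3' of them;
    positions inside an ``lrg_insertion`` have no assembly counterpart and
    raise :class:`UnmappableDiffError`. Positions between spans raise
    :class:`UnmappedGapError`; positions outside every span's range raise
    :class:`OutOfRangeError`. Mismatch differences shift nothing.
    """
    if not mapping.spans:
        raise OutOfRangeError("mapping has no spans")
    lo = mapping.spans[0].lrg_start
    hi = mapping.spans[-1].lrg_end
    if not lo <= g_pos <= hi:
        raise OutOfRangeError(
            f"LRG position {g_pos} outside the mapped range [{lo}, {hi}]"
        )
    span = next(
        (s for s in mapping.spans if s.lrg_start <= g_pos <= s.lrg_end), None
    )
    if span is None:
        raise UnmappedGapError(
            f"LRG position {g_pos} falls between alignment spans "
            f"(unaligned on {mapping.assembly})"
        )
    shift = 0
    for d in _span_diffs(mapping, span):
        if d.kind == "lrg_insertion":
            if d.lrg_start <= g_pos <= d.lrg_end:
                raise UnmappableDiffError(
                    f"LRG position {g_pos} lies inside an LRG-only insertion; "
                    f"no {mapping.assembly} counterpart"
                )
            if d.lrg_end < g_pos:
                shift -= len(d.lrg_allele)
        elif d.kind == "assembly_insertion":
            if d.lrg_start < g_pos:
                shift += len(d.other_allele)
    off = (g_pos - span.lrg_start) + shift
    if span.strand >= 0:
        return span.other_start + off, 1
    return span.other_end - off, -1


def assembly_to_lrg(mapping: AssemblyMapping, pos: int) -> int:
    """Map an assembly position back to the LRG; inverse of
    :func:`lrg_to_assembly` on mappable positions.

    Positions inside an ``assembly_insertion`` difference have no LRG
    counterpart and raise :class:`UnmappableDiffError`.
    """
    if not mapping.spans:
        raise OutOfRangeError("mapping has no spans")
    span = next(
        (s for s in mapping.spans if s.other_start <= pos <= s.other_end), None
    )
    if span is None:
        starts = [s.other_start for s in mapping.spans]
        ends = [s.other_end for s in mapping.spans]
        if min(starts) <= pos <= max(ends):
            raise UnmappedGapError(
                f"{mapping.assembly} position {pos} falls between alignment spans"
            )
        raise OutOfRangeError(
            f"{mapping.assembly} position {pos} outside the mapped range"
        )
    if span.strand >= 0:
        off = pos - span.other_start
    else:
        off = span.other_end - pos
    # walk diffs in LRG order, tracking the assembly offset at each boundary
    shift = 0
    for d in _span_diffs(mapping, span):
        if d.kind == "assembly_insertion":
            start_off = (d.lrg_start - span.lrg_start) + shift + 1
            if start_off <= off <= start_off + len(d.other_allele) - 1:
                raise UnmappableDiffError(
                    f"{mapping.assembly} position {pos} lies inside an "
                    "assembly-only insertion; no LRG counterpart"
                )
            if off >= start_off:
                shift += len(d.other_allele)
        elif d.kind == "lrg_insertion":
            boundary_off = (d.lrg_start - span.lrg_start) + shift
            if off >= boundary_off:
                shift -= len(d.lrg_allele)
    return span.lrg_start + (off - shift)
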