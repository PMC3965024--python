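"""Parse, render and convert HGVS expressions anchored on LRG accessions.

Supported grammar (v1): single-nucleotide substitutions in genomic
(``LRG_1:g.8463G>C``), coding (``LRG_1t1:c.572G>C``) and non-coding
(``LRG_163t1:n.5C>T``) coordinates, and protein missense with 3-letter
amino-acid codes (``LRG_1p1:p.Gly191Ala``). The reference selector is the
versionless accession — accession versions do not exist in this scheme, so
``LRG_1.2`` is rejected outright.

Deletions, duplications, insertions and other variant classes parse to a
structured :class:`UnsupportedVariant` (so files containing them survive a
round trip) rather than a hard error.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Union

from .coords import (
    AA_3LETTER,
    CdnaCoord,
    CoordinateError,
    ProteinCoord,
    RefAlleleMismatch,
    c_to_g,
    g_to_c,
    g_to_n,
    n_to_g,
    predict_protein_change,
)
from .model import LrgRecord

__all__ = [
    "VariantDescription",
    "UnsupportedVariant",
    "HgvsParseError",
    "ConversionError",
    "parse_hgvs",
    "format_hgvs",
    "convert_variant",
]


class HgvsParseError(ValueError):
    """The expression does not fit the accepted LRG-anchored grammar."""


class ConversionError(ValueError):
    """The requested coordinate-system conversion cannot be performed."""


@dataclass(frozen=True)
class VariantDescription:
    """A parsed substitution: reference selector, coordinate system,
    position and alleles.

    ``selector`` is ``None`` for g., a transcript name (``t1``) for c./n.
    and a protein name (``p1``) for p. ``position`` is an ``int`` for g./n.,
    a :class:`~lrgkit.coords.CdnaCoord` for c. and a
    :class:`~lrgkit.coords.ProteinCoord` (which carries its own alleles) for
    p., in which case ``ref_allele``/``alt_allele`` are ``None``.
    """

    lrg_id: str
    selector: Optional[str]
    system: str  # "g", "c", "n" or "p"
    position: Union[int, CdnaCoord, ProteinCoord]
    ref_allele: Optional[str] = None
    alt_allele: Optional[str] = None


@dataclass(frozen=True)
class UnsupportedVariant:
    """A syntactically plausible expression of a variant class outside the
    v1 grammar (del/dup/ins/inv/delins/repeats); kept verbatim so it can be
    re-rendered unchanged."""

    raw: str
    lrg_id: str
    selector: Optional[str]
    system: str
    payload: str


_PREFIX_RE = re.compile(r"^(LRG_\d+)((?:t|p)\d+)?:([a-z])\.(.+)$")
_VERSIONED_RE = re.compile(r"^LRG_\d+\.\d+")
_NT_SUB_RE = re.compile(r"^([ACGT])>([ACGT])$")
_C_POS_RE = re.compile(r"^(-?\d+|\*\d+)([+-]\d+)?")
_G_POS_RE = re.compile(r"^(\d+)")
_P_RE = re.compile(r"^([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2}|=)$")
_P_1LETTER_RE = re.compile(r"^[A-Z*]\d+[A-Z*=]$")
_UNSUPPORTED_RE = re.compile(r"(del|dup|ins|inv|\[|\()")

_AA3 = set(AA_3LETTER.values())


def _parse_c_position(text: str) -> tuple[CdnaCoord, str]:
    m = _C_POS_RE.match(text)
    if not m:
        raise HgvsParseError(f"malformed c. position in {text!r}")
    core, off = m.group(1), m.group(2)
    if core.startswith("*"):
        coord = CdnaCoord("utr3", int(core[1:]), int(off or 0))
    elif core.startswith("-"):
        coord = CdnaCoord("utr5", int(core[1:]), int(off or 0))
    else:
        base = int(core)
        if base == 0:
            raise HgvsParseError("c.0 does not exist: HGVS counting has no zero")
        coord = CdnaCoord("cds", base, int(off or 0))
    return coord, text[m.end() :]


def parse_hgvs(expr: str) -> Union[VariantDescription, UnsupportedVariant]:
    """Parse an LRG-anchored HGVS expression.

    Accepts exactly ``<accession><selector?>:<system>.<position><ref>><alt>``
    for nucleotide systems and ``<accession><p-selector>:p.<Aaa><N><Aaa|=>``
    for protein, with surrounding whitespace tolerated. Raises
    :class:`HgvsParseError` with a pointed message otherwise; non-substitution
    variant classes return an :class:`UnsupportedVariant` instead.
    """
    raw = expr.strip()
    if _VERSIONED_RE.match(raw):
        raise HgvsParseError(
            f"versioned accession in {raw!r}: LRG accessions are never "
            "versioned; a changed locus gets a new accession"
        )
    m = _PREFIX_RE.match(raw)
    if not m:
        raise HgvsParseError(
            f"cannot parse {raw!r}: expected "
            "'LRG_<n>[t<k>|p<k>]:<g|c|n|p>.<change>'"
        )
    lrg_id, selector, system, rest = m.groups()

    if system not in "gcnp":
        raise HgvsParseError(f"unknown coordinate system {system!r} in {raw!r}")
    if system == "g" and selector:
        raise HgvsParseError(
            f"g. positions are on the record's genomic sequence; drop the "
            f"selector {selector!r}"
        )
    if system in "cn" and (not selector or not selector.startswith("t")):
        raise HgvsParseError(
            f"{system}. requires a transcript selector (e.g. "
            f"'{lrg_id}t1:{system}.{rest}')"
        )
    if system == "p" and (not selector or not selector.startswith("p")):
        raise HgvsParseError(
            f"p. requires a protein selector (e.g. '{lrg_id}p1:p.{rest}')"
        )

    if system == "p":
        pm = _P_RE.match(rest)
        if not pm:
            if _P_1LETTER_RE.match(rest):
                raise HgvsParseError(
                    f"cannot parse protein change {rest!r}: use 3-letter "
                    "amino-acid codes (e.g. 'Gly191Ala', not 'G191A')"
                )
            if _UNSUPPORTED_RE.search(rest):
                return UnsupportedVariant(raw, lrg_id, selector, system, rest)
            raise HgvsParseError(f"malformed protein change {rest!r}")
        ref3, res, alt3 = pm.groups()
        if ref3 not in _AA3 or (alt3 != "=" and alt3 not in _AA3):
            raise HgvsParseError(f"unknown amino-acid code in {rest!r}")
        pc = ProteinCoord(int(res), ref3, ref3 if alt3 == "=" else alt3)
        return VariantDescription(lrg_id, selector, "p", pc)

    if system == "c":
        coord, tail = _parse_c_position(rest)
        position: Union[int, CdnaCoord] = coord
    else:
        gm = _G_POS_RE.match(rest)
        if not gm:
            raise HgvsParseError(f"malformed {system}. position in {raw!r}")
        position = int(gm.group(1))
        if position == 0:
            raise HgvsParseError(
                f"{system}.0 does not exist: HGVS counting has no zero"
            )
        tail = rest[gm.end() :]

    sub = _NT_SUB_RE.match(tail)
    if not sub:
        if _UNSUPPORTED_RE.search(tail):
            return UnsupportedVariant(raw, lrg_id, selector, system, rest)
        raise HgvsParseError(
            f"malformed substitution {tail!r} in {raw!r}: expected '<ref>><alt>'"
        )
    ref, alt = sub.groups()
    if ref == alt:
        raise HgvsParseError(
            f"reference and alternate alleles are identical in {raw!r}"
        )
    return VariantDescription(lrg_id, selector, system, position, ref, alt)


def format_hgvs(v: Union[VariantDescription, UnsupportedVariant]) -> str:
    """Render a variant back to its canonical string;
    ``format_hgvs(parse_hgvs(s)) == s`` for every accepted ``s``."""
    if isinstance(v, UnsupportedVariant):
        return v.raw
    sel = v.selector or ""
    if v.system == "p":
        return f"{v.lrg_id}{sel}:p.{v.position}"
    return (
        f"{v.lrg_id}{sel}:{v.system}.{v.position}{v.ref_allele}>{v.alt_allele}"
    )


# ---------------------------------------------------------------------------
# conversion


def _resolve_transcript(record: LrgRecord, v: VariantDescription, transcript):
    if v.selector and v.selector.startswith("t"):
        name = v.selector
    elif transcript is not None:
        name = transcript
    else:
        name = "t1"
    try:
        return record.fixed.transcript(name)
    except KeyError:
        raise ConversionError(
            f"{record.lrg_id} has no transcript {name!r}"
        ) from None


def _check_g_ref(record: LrgRecord, g_pos: int, ref: str) -> None:
    seq = record.fixed.genomic_sequence
    if not 1 <= g_pos <= len(seq):
        raise ConversionError(
            f"g.{g_pos} outside the {len(seq)}-bp genomic sequence"
        )
    if seq[g_pos - 1] != ref:
        raise RefAlleleMismatch(seq[g_pos - 1], ref, f"g.{g_pos}")


def _to_genomic(record: LrgRecord, v: VariantDescription, transcript) -> int:
    """Genomic position of a nucleotide variant, ref allele verified."""
    if v.system == "g":
        g = v.position
    elif v.system == "c":
        g = c_to_g(_resolve_transcript(record, v, transcript), v.position)
    elif v.system == "n":
        g = n_to_g(_resolve_transcript(record, v, transcript), v.position)
    else:
        raise ConversionError(
            "a protein change cannot be converted back to nucleotide "
            "coordinates (the causative codon position is ambiguous)"
        )
    _check_g_ref(record, g, v.ref_allele)
    return g


def convert_variant(
    record: LrgRecord,
    v: VariantDescription,
    target_system: str,
    transcript: Optional[str] = None,
) -> VariantDescription:
    """Re-express a variant in another coordinate system of the same record.

    Reachable targets: g<->c, g<->n, and c->p (or g->p through the coding
    transcript). ``transcript`` picks the transcript when the input is a g.
    variant and the record has several (default ``t1``). The reference
    allele is verified against the record's sequence; p. inputs are rejected
    as ambiguous.
    """
    if isinstance(v, UnsupportedVariant):
        raise ConversionError(f"unsupported variant class: {v.raw!r}")
    if v.lrg_id != record.lrg_id:
        raise ConversionError(
            f"variant references {v.lrg_id}, record is {record.lrg_id}"
        )
    if target_system not in "gcnp":
        raise ConversionError(f"unknown target system {target_system!r}")

    try:
        g = _to_genomic(record, v, transcript)
    except CoordinateError as exc:
        raise ConversionError(str(exc)) from exc

    if target_system == "g":
        return VariantDescription(
            record.lrg_id, None, "g", g, v.ref_allele, v.alt_allele
        )

    tr = _resolve_transcript(record, v, transcript)
    try:
        if target_system == "c":
            coord = g_to_c(tr, g)
            return VariantDescription(
                record.lrg_id, tr.name, "c", coord, v.ref_allele, v.alt_allele
            )
        if target_system == "n":
            n = g_to_n(tr, g)
            return VariantDescription(
                record.lrg_id, tr.name, "n", n, v.ref_allele, v.alt_allele
            )
        # target p: go through c. on the coding transcript
        coord = g_to_c(tr, g)
        pc = predict_protein_change(tr, coord, v.ref_allele, v.alt_allele)
        pname = f"p{tr.name[1:]}"
        return VariantDescription(record.lrg_id, pname, "p", pc)
    except CoordinateError as exc:
        raise ConversionError(str(exc)) from exc
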