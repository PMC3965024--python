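"""HGVS parsing/rendering and cross-system variant conversion."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lrgkit import (
    CdnaCoord,
    ConversionError,
    HgvsParseError,
    UnsupportedVariant,
    convert_variant,
    format_hgvs,
    parse_hgvs,
)

from conftest import fixture_record, small_fixture_record

CANONICAL_EXAMPLES = [
    "LRG_1:g.8463G>C",
    "LRG_1t1:c.572G>C",
    "LRG_163t1:n.5C>T",
    "LRG_1p1:p.Gly191Ala",
]


class TestParse:
    def test_genomic_substitution_fields(self):
        v = parse_hgvs("LRG_1:g.8463G>C")
        assert (v.lrg_id, v.selector, v.system) == ("LRG_1", None, "g")
        assert (v.position, v.ref_allele, v.alt_allele) == (8463, "G", "C")

    def test_coding_substitution_fields(self):
        v = parse_hgvs("LRG_1t1:c.572G>C")
        assert (v.lrg_id, v.selector, v.system) == ("LRG_1", "t1", "c")
        assert v.position == CdnaCoord("cds", 572)

    def test_noncoding_substitution_fields(self):
        v = parse_hgvs("LRG_163t1:n.5C>T")
        assert (v.lrg_id, v.selector, v.system, v.position) == (
            "LRG_163", "t1", "n", 5,
        )

    def test_protein_missense_fields(self):
        v = parse_hgvs("LRG_1p1:p.Gly191Ala")
        assert (v.lrg_id, v.selector, v.system) == ("LRG_1", "p1", "p")
        assert (v.position.residue, v.position.ref_aa, v.position.alt_aa) == (
            191, "Gly", "Ala",
        )

    @pytest.mark.parametrize(
        "expr,fragment",
        [
            ("LRG_1:c.5A>T", "transcript selector"),
            ("LRG_1t1:g.5A>T", "selector"),
            ("LRG_1:n.5A>T", "transcript selector"),
            ("LRG_1t1:p.Gly191Ala", "protein selector"),
            ("LRG_1.2:g.5A>T", "version"),
            ("NM_000088.3:c.5A>T", "LRG"),
            ("LRG_1:g.0A>T", "zero"),
            ("LRG_1:g.5A>A", "identical"),
            ("LRG_1p1:p.G191A", "3-letter"),
        ],
    )
    def test_grammar_violations_carry_pointed_messages(self, expr, fragment):
        with pytest.raises(HgvsParseError, match=fragment):
            parse_hgvs(expr)

    @pytest.mark.parametrize(
        "expr", ["LRG_1:g.8460_8462del", "LRG_1t1:c.10dup", "LRG_1t1:c.10_11insA"]
    )
    def test_other_variant_classes_become_structured_unsupported(self, expr):
        v = parse_hgvs(expr)
        assert isinstance(v, UnsupportedVariant)
        assert format_hgvs(v) == expr  # survives a round trip verbatim

    @pytest.mark.parametrize(
        "expr,coord",
        [
            ("LRG_5t1:c.-14G>A", CdnaCoord("utr5", 14)),
            ("LRG_5t1:c.*7G>A", CdnaCoord("utr3", 7)),
            ("LRG_5t1:c.88+1G>A", CdnaCoord("cds", 88, 1)),
            ("LRG_5t1:c.89-2G>A", CdnaCoord("cds", 89, -2)),
            ("LRG_5t1:c.-14+3G>A", CdnaCoord("utr5", 14, 3)),
        ],
    )
    def test_utr_and_intronic_positions(self, expr, coord):
        assert parse_hgvs(expr).position == coord


class TestFormat:
    @pytest.mark.parametrize("expr", CANONICAL_EXAMPLES)
    def test_canonical_examples_roundtrip_byte_identically(self, expr):
        assert format_hgvs(parse_hgvs(expr)) == expr

    def test_rendering_rules(self):
        assert str(CdnaCoord("utr5", 14)) == "-14"
        assert str(CdnaCoord("cds", 88, 1)) == "88+1"
        assert str(CdnaCoord("utr3", 7, -2)) == "*7-2"


@st.composite
def valid_expressions(draw):
    acc = f"LRG_{draw(st.integers(1, 9999))}"
    system = draw(st.sampled_from("gcnp"))
    if system == "p":
        aas = ["Ala", "Gly", "Cys", "Trp", "Arg", "Ser", "Ter"]
        ref = draw(st.sampled_from(aas))
        # a same-as-reference allele is canonically spelled "=", never Aaa
        alt = draw(st.sampled_from([a for a in aas if a != ref] + ["="]))
        return f"{acc}p{draw(st.integers(1, 9))}:p.{ref}{draw(st.integers(1, 5000))}{alt}"
    ref, alt = draw(
        st.sampled_from([(a, b) for a in "ACGT" for b in "ACGT" if a != b])
    )
    if system == "g":
        return f"{acc}:g.{draw(st.integers(1, 10**6))}{ref}>{alt}"
    sel = f"t{draw(st.integers(1, 9))}"
    if system == "n":
        return f"{acc}{sel}:n.{draw(st.integers(1, 10**4))}{ref}>{alt}"
    core = draw(
        st.one_of(
            st.integers(1, 10**4).map(str),
            st.integers(1, 500).map(lambda n: f"-{n}"),
            st.integers(1, 500).map(lambda n: f"*{n}"),
        )
    )
    off = draw(
        st.one_of(
            st.just(""),
            st.integers(1, 99).map(lambda k: f"+{k}"),
            st.integers(1, 99).map(lambda k: f"-{k}"),
        )
    )
    return f"{acc}{sel}:c.{core}{off}{ref}>{alt}"


@settings(max_examples=300, derandomize=True, deadline=None)
@given(valid_expressions())
def test_parse_and_format_are_mutual_inverses(expr):
    assert format_hgvs(parse_hgvs(expr)) == expr


class TestConvert:
    def test_g_at_cds_start_becomes_c1_with_same_alleles(self):
        _, _, rec = fixture_record(1, lrg_number=1)
        t1 = rec.fixed.transcript("t1")
        from lrgkit import c_to_g

        g = c_to_g(t1, CdnaCoord("cds", 1))
        ref = rec.fixed.genomic_sequence[g - 1]
        alt = "A" if ref != "A" else "G"
        out = convert_variant(rec, parse_hgvs(f"LRG_1:g.{g}{ref}>{alt}"), "c")
        assert format_hgvs(out) == f"LRG_1t1:c.1{ref}>{alt}"

    def test_gly_codon_substitution_converts_to_the_matching_p(self):
        # c. at codon position 2 of a Gly codon, G>C -> Gly...Ala
        from lrgkit import (
            AssemblyMapping,
            FixedSection,
            FixedTranscript,
            LrgRecord,
            MappingSpan,
            UpdatableSection,
            assign_exon_numbers,
        )
        from lrgkit.model import ExonSpan, FixedProtein, translate_cds

        cds = "ATG" + "GAA" * 189 + "GGT" + "TAA"  # Gly at residue 191
        t1 = FixedTranscript(
            "t1", (ExonSpan(1, len(cds)),), cds, (1, len(cds)),
            FixedProtein("p1", translate_cds(cds)[:-1]),
        )
        rec = LrgRecord(
            "LRG_1", "public",
            FixedSection("GLY1", (), cds, (t1,), assign_exon_numbers([t1])),
            UpdatableSection(),
        )
        out = convert_variant(rec, parse_hgvs("LRG_1t1:c.572G>C"), "p")
        assert format_hgvs(out) == "LRG_1p1:p.Gly191Ala"

    def test_round_trip_g_to_c_to_g_preserves_the_variant(self):
        _, _, rec = small_fixture_record(2, lrg_number=1)
        t1 = rec.fixed.transcript("t1")
        seq = rec.fixed.genomic_sequence
        for g in range(t1.exons[0].start, t1.exons[-1].end + 1, 13):
            ref = seq[g - 1]
            alt = "C" if ref != "C" else "T"
            v = parse_hgvs(f"LRG_1:g.{g}{ref}>{alt}")
            back = convert_variant(rec, convert_variant(rec, v, "c"), "g")
            assert back == v

    def test_fixture_wide_g_to_c_to_p_matches_retranslation(self):
        from lrgkit import c_to_g
        from lrgkit.model import translate_cds

        _, _, rec = small_fixture_record(6, lrg_number=1)
        t1 = rec.fixed.transcript("t1")
        cs, ce = t1.coding_region
        cds = t1.cdna_sequence[cs - 1 : ce]
        seq = rec.fixed.genomic_sequence
        for base in range(1, len(cds) + 1, 5):
            g = c_to_g(t1, CdnaCoord("cds", base))
            ref = seq[g - 1]
            alt = "C" if ref != "C" else "T"
            out = convert_variant(rec, parse_hgvs(f"LRG_1:g.{g}{ref}>{alt}"), "p")
            mutated = cds[: base - 1] + alt + cds[base:]
            old_aa, new_aa = translate_cds(cds), translate_cds(mutated)
            r = out.position.residue
            assert (old_aa[r - 1] == new_aa[r - 1]) == out.position.synonymous

    def test_ref_allele_mismatch_is_reported_with_both(self):
        _, _, rec = fixture_record(1, lrg_number=1)
        seq = rec.fixed.genomic_sequence
        wrong = "A" if seq[99] != "A" else "T"
        alt = "G" if wrong != "G" else "C"
        with pytest.raises(ConversionError, match="mismatch"):
            convert_variant(rec, parse_hgvs(f"LRG_1:g.100{wrong}>{alt}"), "c")

    def test_protein_input_cannot_be_converted_back(self):
        _, _, rec = fixture_record(1, lrg_number=1)
        with pytest.raises(ConversionError, match="ambiguous"):
            convert_variant(rec, parse_hgvs("LRG_1p1:p.Gly2Ala"), "c")

    def test_record_accession_must_match(self):
        _, _, rec = fixture_record(1, lrg_number=1)
        with pytest.raises(ConversionError, match="LRG_2"):
            convert_variant(rec, parse_hgvs("LRG_2:g.5A>T"), "c")
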