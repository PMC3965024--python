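"""Coordinate arithmetic: g<->c/n conversions against a base-by-base scan
oracle, codon arithmetic, protein-consequence prediction against whole-CDS
retranslation, and diff-aware assembly remapping against an
alignment-expansion oracle."""

import random

import pytest

from lrgkit import (
    CdnaCoord,
    ExonSpan,
    FixedTranscript,
    assembly_to_lrg,
    c_to_g,
    codon_of,
    g_to_c,
    g_to_n,
    lrg_to_assembly,
    n_to_g,
    predict_protein_change,
)
from lrgkit.coords import (
    CodingTranscriptError,
    NonCodingTranscriptError,
    OutOfRangeError,
    RefAlleleMismatch,
    UnmappableDiffError,
    UnmappedGapError,
)
from lrgkit.model import translate_cds

from conftest import small_fixture_record
from oracles import align_columns, random_mapping, scan_c_coordinates


class TestGToC:
    def test_cds_first_base_is_c1_and_preceding_base_is_c_minus_1(self, toy_record):
        t1 = toy_record.fixed.transcript("t1")
        # CDS starts at cDNA position 4 = genomic 14 (exon1 starts at 11)
        assert g_to_c(t1, 14) == CdnaCoord("cds", 1)
        assert g_to_c(t1, 13) == CdnaCoord("utr5", 1)  # no zero in HGVS

    def test_star_1_is_first_base_after_the_stop_codon(self, toy_record):
        t1 = toy_record.fixed.transcript("t1")
        # CDS ends at cDNA 24 = genomic 42; genomic 43 is *1
        assert g_to_c(t1, 42) == CdnaCoord("cds", 21)
        assert g_to_c(t1, 43) == CdnaCoord("utr3", 1)
        assert c_to_g(t1, CdnaCoord("utr3", 1)) == 43

    @pytest.mark.parametrize("seed", range(6))
    def test_every_position_agrees_with_the_scan_oracle(self, seed):
        _, _, rec = small_fixture_record(seed)
        t1 = rec.fixed.transcript("t1")
        seq_len = len(rec.fixed.genomic_sequence)
        expected = scan_c_coordinates(t1, seq_len)
        for g in range(1, seq_len + 1):
            assert str(g_to_c(t1, g)) == expected[g], f"g={g}"

    def test_noncoding_transcript_is_rejected(self):
        t = FixedTranscript("t1", (ExonSpan(1, 30),), "A" * 30)
        with pytest.raises(NonCodingTranscriptError):
            g_to_c(t, 5)


class TestCToG:
    @pytest.mark.parametrize("seed", range(6))
    def test_inverse_of_g_to_c_over_the_whole_sequence(self, seed):
        _, _, rec = small_fixture_record(seed)
        t1 = rec.fixed.transcript("t1")
        for g in range(1, len(rec.fixed.genomic_sequence) + 1):
            assert c_to_g(t1, g_to_c(t1, g)) == g

    def test_simple_offset_arithmetic_on_a_single_exon_cds(self):
        # CDS starting at LRG position S on one exon: c.572 -> S + 571
        cds = "ATG" + "GAA" * 190 + "TAA"
        t = FixedTranscript(
            "t1", (ExonSpan(101, 101 + len(cds) - 1),), cds,
            coding_region=(1, len(cds)),
        )
        assert c_to_g(t, CdnaCoord("cds", 572)) == 101 + 571

    def test_positions_beyond_the_cds_are_rejected(self, toy_record):
        t1 = toy_record.fixed.transcript("t1")
        with pytest.raises(OutOfRangeError):
            c_to_g(t1, CdnaCoord("cds", 10_000))

    def test_intronic_offset_larger_than_the_intron_is_rejected(self, toy_record):
        t1 = toy_record.fixed.transcript("t1")  # intron 23-30, length 8
        assert c_to_g(t1, CdnaCoord("cds", 9, offset=4)) == 26
        with pytest.raises(OutOfRangeError):
            c_to_g(t1, CdnaCoord("cds", 9, offset=9))


class TestNonCoding:
    def _nc(self, rec, name="t2"):
        t = rec.fixed.transcript(name)
        assert t.coding_region is None
        return t

    def test_fifth_exonic_base_is_n5(self):
        _, _, rec = small_fixture_record(4, n_transcripts=2)
        t = self._nc(rec)
        g5 = t.exons[0].start + 4
        assert g_to_n(t, g5) == 5
        assert g_to_n(t, t.exons[0].start) == 1

    @pytest.mark.parametrize("seed", [4, 10, 16])  # seeds with non-coding t2
    def test_all_exonic_positions_agree_with_enumeration(self, seed):
        _, _, rec = small_fixture_record(seed, n_transcripts=2)
        t = self._nc(rec)
        n = 0
        for ex in t.exons:
            for g in range(ex.start, ex.end + 1):
                n += 1
                assert g_to_n(t, g) == n
                assert n_to_g(t, n) == g

    def test_intronic_positions_are_rejected(self, toy_record):
        t = FixedTranscript("t1", (ExonSpan(11, 22), ExonSpan(31, 48)),
                            "A" * 30)
        with pytest.raises(OutOfRangeError):
            g_to_n(t, 25)

    def test_coding_transcript_is_redirected_to_c(self, toy_record):
        with pytest.raises(CodingTranscriptError):
            g_to_n(toy_record.fixed.transcript("t1"), 15)


class TestCodonOf:
    @pytest.mark.parametrize(
        "c_base,residue,codon_pos",
        [(572, 191, 2), (1, 1, 1), (3, 1, 3), (4, 2, 1)],
    )
    def test_residue_and_codon_position(self, c_base, residue, codon_pos):
        assert codon_of(c_base) == (residue, codon_pos)

    def test_each_residue_receives_exactly_three_cds_positions(self):
        from collections import Counter

        counts = Counter(codon_of(b)[0] for b in range(1, 301))
        assert all(v == 3 for v in counts.values())
        assert max(counts) == 100


class TestProteinChange:
    def test_gly_codon_g_to_c_at_position_2_yields_ala(self):
        cds = "ATG" + "GGT" + "TAA"  # Met Gly stop
        t = FixedTranscript("t1", (ExonSpan(1, 9),), cds, coding_region=(1, 9))
        pc = predict_protein_change(t, CdnaCoord("cds", 5), "G", "C")
        assert (pc.residue, pc.ref_aa, pc.alt_aa) == (2, "Gly", "Ala")

    def test_synonymous_substitution_is_marked(self):
        cds = "ATG" + "GGT" + "TAA"
        t = FixedTranscript("t1", (ExonSpan(1, 9),), cds, coding_region=(1, 9))
        pc = predict_protein_change(t, CdnaCoord("cds", 6), "T", "C")  # GGT>GGC
        assert pc.synonymous and str(pc) == "Gly2="

    def test_nonsense_substitution_renders_ter(self):
        cds = "ATG" + "TGC" + "TAA"
        t = FixedTranscript("t1", (ExonSpan(1, 9),), cds, coding_region=(1, 9))
        pc = predict_protein_change(t, CdnaCoord("cds", 6), "C", "A")  # TGC>TGA
        assert pc.alt_aa == "Ter"

    def test_ref_allele_mismatch_reports_both_alleles(self, toy_record):
        t1 = toy_record.fixed.transcript("t1")
        with pytest.raises(RefAlleleMismatch) as err:
            predict_protein_change(t1, CdnaCoord("cds", 1), "C", "T")
        assert err.value.expected == "A" and err.value.given == "C"

    @pytest.mark.parametrize("seed", [0, 8])
    def test_every_cds_position_agrees_with_full_retranslation(self, seed):
        # oracle: mutate the cDNA, retranslate the whole protein, diff
        _, _, rec = small_fixture_record(seed)
        t1 = rec.fixed.transcript("t1")
        cs, ce = t1.coding_region
        cds = t1.cdna_sequence[cs - 1 : ce]
        old_aa = translate_cds(cds)
        for base in range(1, len(cds) + 1):
            ref = cds[base - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                mutated = cds[: base - 1] + alt + cds[base:]
                new_aa = translate_cds(mutated)
                pc = predict_protein_change(t1, CdnaCoord("cds", base), ref, alt)
                assert old_aa[pc.residue - 1] != new_aa[pc.residue - 1] or pc.synonymous
                from lrgkit.coords import AA_3LETTER

                assert pc.ref_aa == AA_3LETTER[old_aa[pc.residue - 1]]
                assert pc.alt_aa == AA_3LETTER[new_aa[pc.residue - 1]]
                # no other residue may change
                diffs = [
                    i for i, (a, b) in enumerate(zip(old_aa, new_aa)) if a != b
                ]
                assert diffs in ([], [pc.residue - 1])


class TestRemap:
    def test_identity_mapping_is_the_identity(self):
        from lrgkit import AssemblyMapping, MappingSpan

        m = AssemblyMapping("A", "c", (MappingSpan(1, 100, 1, 100, 1),))
        assert lrg_to_assembly(m, 37) == (37, 1)
        assert assembly_to_lrg(m, 37) == 37

    def test_minus_strand_reflection(self):
        from lrgkit import AssemblyMapping, MappingSpan

        m = AssemblyMapping("A", "c", (MappingSpan(1, 100, 1001, 1100, -1),))
        assert lrg_to_assembly(m, 1) == (1100, -1)
        assert lrg_to_assembly(m, 100) == (1001, -1)
        assert assembly_to_lrg(m, 1100) == 1
        assert assembly_to_lrg(m, 1001) == 100

    @pytest.mark.parametrize("seed", range(40))
    def test_random_configurations_agree_with_the_expansion_oracle(self, seed):
        mapping = random_mapping(random.Random(seed))
        columns = align_columns(mapping)
        lrg_to_asm = {l: a for l, a in columns if l is not None and a is not None}
        lrg_unmappable = {l for l, a in columns if l is not None and a is None}
        asm_unmappable = {a for l, a in columns if l is None and a is not None}
        lo = mapping.spans[0].lrg_start
        hi = mapping.spans[-1].lrg_end
        covered = {
            g for s in mapping.spans for g in range(s.lrg_start, s.lrg_end + 1)
        }
        for g in range(lo, hi + 1):
            if g in lrg_to_asm:
                pos, strand = lrg_to_assembly(mapping, g)
                assert pos == lrg_to_asm[g], f"seed={seed} g={g}"
                assert strand == mapping.strand
                assert assembly_to_lrg(mapping, pos) == g
            elif g in lrg_unmappable:
                with pytest.raises(UnmappableDiffError):
                    lrg_to_assembly(mapping, g)
            else:
                assert g not in covered
                with pytest.raises(UnmappedGapError):
                    lrg_to_assembly(mapping, g)
        for a in asm_unmappable:
            with pytest.raises(UnmappableDiffError):
                assembly_to_lrg(mapping, a)

    def test_unmappable_count_conservation(self):
        # unmappable LRG positions == inter-span gaps + lrg_insertion lengths
        for seed in range(15):
            mapping = random_mapping(random.Random(1000 + seed))
            lo = mapping.spans[0].lrg_start
            hi = mapping.spans[-1].lrg_end
            n_unmappable = 0
            for g in range(lo, hi + 1):
                try:
                    lrg_to_assembly(mapping, g)
                except (UnmappableDiffError, UnmappedGapError):
                    n_unmappable += 1
            gap_len = (hi - lo + 1) - sum(
                s.lrg_end - s.lrg_start + 1 for s in mapping.spans
            )
            ins_len = sum(
                len(d.lrg_allele)
                for d in mapping.diffs
                if d.kind == "lrg_insertion"
            )
            assert n_unmappable == gap_len + ins_len

    def test_out_of_range_is_distinct_from_gap(self):
        from lrgkit import AssemblyMapping, MappingSpan

        m = AssemblyMapping(
            "A", "c",
            (MappingSpan(10, 20, 110, 120, 1), MappingSpan(31, 40, 131, 140, 1)),
        )
        with pytest.raises(UnmappedGapError):
            lrg_to_assembly(m, 25)
        with pytest.raises(OutOfRangeError):
            lrg_to_assembly(m, 5)
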