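import pytest

from lrgkit import (
    AssemblyMapping,
    ExonSpan,
    FixedProtein,
    FixedSection,
    FixedTranscript,
    FixtureSpec,
    LrgRecord,
    MappingSpan,
    UpdatableSection,
    assign_exon_numbers,
    build_record,
    make_fixture,
)

# A tiny hand-built record whose every coordinate is known by inspection:
#   flank(10) + exon1 11-22 + intron 23-30 + exon2 31-48 + flank 49-60
#   cDNA = TTT ATGGGTCCC GCATGCAAATAA GGGGGG  (5'UTR=3, CDS=21, 3'UTR=6)
#   protein = MGPACK
TOY_SEQ = (
    "ACGTACGTAC" "TTTATGGGTCCC" "AAAAAAAA" "GCATGCAAATAAGGGGGG" "ACGTACGTACGT"
)
TOY_EXONS = (ExonSpan(11, 22), ExonSpan(31, 48))


def make_toy_record(lrg_id="LRG_9001", status="public"):
    cdna = TOY_SEQ[10:22] + TOY_SEQ[30:48]
    t1 = FixedTranscript(
        "t1", TOY_EXONS, cdna, coding_region=(4, 24),
        protein=FixedProtein("p1", "MGPACK"),
    )
    fixed = FixedSection(
        hgnc_symbol="TOY1",
        requesters=("Toy diagnostics consortium",),
        genomic_sequence=TOY_SEQ,
        transcripts=(t1,),
        numbering=assign_exon_numbers([t1]),
    )
    mapping = AssemblyMapping(
        assembly="GRCh37", other_name="chr17",
        spans=(MappingSpan(1, 60, 1001, 1060, 1),),
    )
    return LrgRecord(lrg_id, status, fixed, UpdatableSection(mappings=(mapping,)))


@pytest.fixture
def toy_record():
    return make_toy_record()


def fixture_record(seed, lrg_number=9001, flank_up=5000, flank_down=2000, **spec_kw):
    """Build a full synthetic record from a seeded genome + gene model."""
    genome, model = make_fixture(FixtureSpec(seed=seed, **spec_kw))
    return genome, model, build_record(
        genome, model, lrg_number=lrg_number,
        flank_up=flank_up, flank_down=flank_down,
    )


# small fixtures (<=10 kb LRG sequence) used for exhaustive per-base scans
def small_fixture_record(seed, **kw):
    kw.setdefault("genome_length", 6000)
    kw.setdefault("n_exons", 3)
    kw.setdefault("intron_length_range", (40, 200))
    return fixture_record(seed, flank_up=300, flank_down=150, **kw)


@pytest.fixture
def record9001():
    return fixture_record(7)[2]
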